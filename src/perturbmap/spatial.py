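"""Spatial prioritization of perturbation responses.

For each spatial barcode, take its k nearest neighbours from each of two
experimental conditions, train a random forest to tell the conditions apart
within that neighbourhood, and score the separability as a cross-validated
AUC. Repeating the procedure for every barcode yields an AUC map over the
common coordinate system; repeating the cross-validation many times per
barcode (default 50) converges the per-barcode estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from ._forest import rf_cv_auc, stable_rng
from .celltype import select_variable_genes
from .datamodel import FeatureMatrix, SpatialCoordinates

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialParams",
    "BarcodeScore",
    "knn_per_condition",
    "barcode_auc",
    "prioritize_map",
    "convergence_diagnostic",
    "scores_frame",
]


@dataclass
class SpatialParams:
    """Configuration of per-barcode neighbourhood scoring.

    ``k`` neighbours are taken from each condition (so neighbourhoods hold
    2k barcodes); the 3-fold cross-validation withholds one third of the
    labels per fold and is repeated ``n_repeats`` times.
    """

    k: int = 20
    n_repeats: int = 50
    n_folds: int = 3
    n_trees: int = 100
    var_quantile: float = 0.5
    rng_seed: int = 0
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k < self.n_folds:
            raise ValueError("k must be >= n_folds")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.distance != "euclidean":
            raise ValueError("only Euclidean distance is supported")


@dataclass
class BarcodeScore:
    barcode: str
    mean_auc: float
    auc_samples: np.ndarray
    neighbourhood: list[str]
    skipped: bool = False
    reason: str = ""


def knn_per_condition(
    center: str,
    coords: SpatialCoordinates,
    conditions: pd.Series,
    k: int,
) -> dict[str, list[str]]:
    """The k nearest barcodes to ``center`` from each condition.

    The center barcode is eligible for its own condition's set. Distance
    ties are broken by lexicographic barcode ID so neighbourhoods are
    platform-independent. Raises ``ValueError`` if either condition has
    fewer than k barcodes.
    """
    conditions = conditions.astype(str)
    levels = sorted(conditions.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly two conditions, got {levels}")
    cx, cy = coords.table.loc[center, ["x", "y"]]
    out: dict[str, list[str]] = {}
    for level in levels:
        members = conditions.index[conditions == level].to_numpy(dtype=object)
        if len(members) < k:
            raise ValueError(f"condition {level!r} has {len(members)} barcodes; need k={k}")
        xy = coords.xy(members)
        d2 = (xy[:, 0] - cx) ** 2 + (xy[:, 1] - cy) ** 2
        lex_rank = np.argsort(np.argsort(members.astype(str)))
        order = np.lexsort((lex_rank, d2))[:k]
        out[level] = [str(b) for b in members[order]]
    return out


def barcode_auc(
    features: FeatureMatrix,
    labels: Sequence[str],
    params: SpatialParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """AUC samples for one neighbourhood: repeated randomized stratified CV.

    Variable features are selected once on the pooled neighbourhood (the
    repeats average cross-validation partition noise, not feature-set
    noise); each repeat re-randomizes the fold assignment.
    """
    labels = np.asarray(labels, dtype=object)
    levels = sorted(set(labels))
    if len(levels) != 2:
        raise ValueError("neighbourhood must contain both conditions")
    keep = select_variable_genes(features, params.var_quantile)
    X = features.values[:, keep]
    y = (labels == levels[1]).astype(np.int64)
    samples = np.empty(params.n_repeats)
    for r in range(params.n_repeats):
        samples[r] = rf_cv_auc(X, y, params.n_folds, params.n_trees, rng)
    return samples


def prioritize_map(
    features: FeatureMatrix,
    coords: SpatialCoordinates,
    conditions: pd.Series,
    params: SpatialParams | None = None,
    score_barcodes: Sequence[str] | None = None,
    exclude_barcodes: Sequence[str] | None = None,
) -> list[BarcodeScore]:
    """Score condition separability at every barcode's location.

    Returns one :class:`BarcodeScore` per requested barcode (all labelled
    barcodes by default), in input order, with un-scoreable barcodes marked
    skipped. Neighbourhoods always draw from the full labelled dataset;
    ``score_barcodes`` restricts only which centers are evaluated (useful
    for scaled-down validation runs). Per-barcode RNG streams are derived
    from (seed, barcode), so the map is independent of evaluation order.
    """
    params = params or SpatialParams()
    conditions = conditions.astype(str)
    exclude = set(exclude_barcodes or ())
    labelled = [
        b for b in features.barcodes if b in conditions.index and b not in exclude
    ]
    missing_coords = [b for b in labelled if b not in coords.table.index]
    if missing_coords:
        raise ValueError(f"coordinates missing for barcodes {missing_coords[:5]}")
    conditions = conditions.loc[labelled]
    levels = sorted(conditions.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly two conditions, got {levels}")
    centers = list(score_barcodes) if score_barcodes is not None else labelled

    counts = conditions.value_counts()
    too_small = [lvl for lvl in levels if counts.get(lvl, 0) < params.k]
    if too_small:
        logger.error(
            "conditions %s have fewer than k=%d barcodes; every barcode skipped",
            too_small,
            params.k,
        )
        return [
            BarcodeScore(b, float("nan"), np.array([]), [], True, "insufficient barcodes")
            for b in centers
        ]

    position = {b: i for i, b in enumerate(features.barcodes)}
    sub_coords = coords.subset(labelled)
    scores: list[BarcodeScore] = []
    for center in centers:
        if center not in conditions.index:
            scores.append(
                BarcodeScore(center, float("nan"), np.array([]), [], True, "no condition label")
            )
            continue
        neigh = knn_per_condition(center, sub_coords, conditions, params.k)
        neighbourhood = neigh[levels[0]] + neigh[levels[1]]
        rows = np.array([position[b] for b in neighbourhood])
        local = FeatureMatrix(
            features.values[rows, :],
            features.feature_ids,
            neighbourhood,
            kind=features.kind,
        )
        labels = [levels[0]] * params.k + [levels[1]] * params.k
        rng = stable_rng(params.rng_seed, "spatial", center)
        samples = barcode_auc(local, labels, params, rng)
        scores.append(
            BarcodeScore(
                barcode=center,
                mean_auc=float(samples.mean()),
                auc_samples=samples,
                neighbourhood=neighbourhood,
            )
        )
    return scores


def convergence_diagnostic(
    scores: Sequence[BarcodeScore],
) -> tuple[pd.DataFrame, float]:
    """Split each barcode's AUC samples in half and compare the half-means.

    Returns per-barcode (first-half mean, second-half mean) plus their
    across-barcode Pearson correlation — the replicate-split check for
    whether the number of CV repeats suffices. A degenerate (constant)
    half-mean vector yields NaN correlation.
    """
    rows = {}
    for s in scores:
        if s.skipped:
            continue
        n = len(s.auc_samples)
        if n < 2 or n % 2:
            raise ValueError("convergence diagnostic requires an even number of repeats >= 2")
        half = n // 2
        rows[s.barcode] = (
            float(np.mean(s.auc_samples[:half])),
            float(np.mean(s.auc_samples[half:])),
        )
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=["first_half", "second_half"])
    a, b = frame["first_half"].to_numpy(), frame["second_half"].to_numpy()
    if len(frame) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("degenerate half-means; correlation undefined")
        return frame, float("nan")
    return frame, float(pearsonr(a, b).statistic)


def scores_frame(scores: Sequence[BarcodeScore], coords: SpatialCoordinates) -> pd.DataFrame:
    """Tabulate barcode scores with their coordinates for output."""
    rows = []
    for s in scores:
        known = s.barcode in coords.table.index
        rows.append(
            {
                "barcode": s.barcode,
                "x": coords.table.at[s.barcode, "x"] if known else np.nan,
                "y": coords.table.at[s.barcode, "y"] if known else np.nan,
                "mean_auc": s.mean_auc,
                "sd_auc": float(np.std(s.auc_samples)) if len(s.auc_samples) else np.nan,
                "n_repeats": len(s.auc_samples),
                "skipped": s.skipped,
                "reason": s.reason,
            }
        )
    return pd.DataFrame(rows)
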