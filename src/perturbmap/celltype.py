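"""Cell-type prioritization.

For each cell type, quantify how separable two experimental conditions are
in expression space: repeatedly draw balanced subsamples of cells, select
variable features, train a random forest to predict the condition, and
summarize out-of-fold performance as an AUC. Cell types responding strongly
to a perturbation become more separable and receive higher AUCs; fixed-size
subsampling makes the scores comparable across cell types of different
abundance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._forest import rf_cv_auc, stable_rng
from .datamodel import FeatureMatrix, ObservationMeta

logger = logging.getLogger(__name__)

__all__ = [
    "PrioritizationParams",
    "CellTypeScore",
    "InsufficientCellsError",
    "select_variable_genes",
    "subsample_balanced",
    "prioritize_cell_types",
    "scale_scores",
]


class InsufficientCellsError(ValueError):
    """A condition lacks enough cells for a balanced subsample."""


@dataclass
class PrioritizationParams:
    """Configuration of the subsample / classify / cross-validate loop."""

    n_subsamples: int = 50
    subsample_size: int = 20
    n_folds: int = 3
    n_trees: int = 100
    var_quantile: float = 0.5
    min_cells_per_condition: int | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.subsample_size < self.n_folds:
            raise ValueError("subsample_size must be >= n_folds")
        if not 0 < self.var_quantile <= 1:
            raise ValueError("var_quantile must lie in (0, 1]")
        if self.min_cells_per_condition is None:
            self.min_cells_per_condition = self.subsample_size


@dataclass
class CellTypeScore:
    cell_type: str
    mean_auc: float
    auc_samples: np.ndarray
    n_cells: dict[str, int]
    skipped: bool = False
    reason: str = ""


def select_variable_genes(
    features: FeatureMatrix | np.ndarray, var_quantile: float
) -> np.ndarray:
    """Return indices of the most variable features.

    Features are ranked by the residual of a locally weighted fit of
    log(variance) on log(mean) — a dispersion measure detrended for the
    mean-variance relationship of expression data. The top ``var_quantile``
    fraction of positive-variance features is kept. When means are not all
    positive (e.g. velocity matrices) or the fit degenerates, ranking falls
    back to raw variance.
    """
    values = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 features")
    mean = values.mean(axis=0)
    var = values.var(axis=0, ddof=1)
    eligible = np.flatnonzero(var > 0)
    if len(eligible) == 0:
        raise ValueError("all features have zero variance")
    if var_quantile >= 1.0:
        return eligible
    score = _dispersion_residual(mean[eligible], var[eligible])
    n_select = max(1, int(np.ceil(var_quantile * len(eligible))))
    # stable: ties broken by feature index
    order = np.lexsort((eligible, -score))
    return np.sort(eligible[order[:n_select]])


def _dispersion_residual(mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    log_var = np.log(var)
    if np.any(mean <= 0) or len(mean) < 10:
        return log_var
    log_mean = np.log(mean)
    if np.ptp(log_mean) == 0:
        return log_var
    from statsmodels.nonparametric.smoothers_lowess import lowess

    trend = lowess(log_var, log_mean, frac=0.3, it=1, return_sorted=False)
    if not np.all(np.isfinite(trend)):
        return log_var
    return log_var - trend


def subsample_balanced(
    barcodes: Sequence[str],
    conditions: Sequence[str],
    size: int,
    rng: np.random.Generator,
) -> list[str]:
    """Sample exactly ``size`` barcodes per condition, without replacement.

    Conditions are processed in sorted label order so draws are reproducible.
    Raises :class:`InsufficientCellsError` when a condition is too small.
    """
    barcodes = np.asarray(barcodes, dtype=object)
    conditions = np.asarray(conditions, dtype=object)
    chosen: list[str] = []
    for level in sorted(set(conditions)):
        pool = barcodes[conditions == level]
        if len(pool) < size:
            raise InsufficientCellsError(
                f"condition {level!r} has {len(pool)} cells; need {size}"
            )
        chosen.extend(rng.choice(pool, size=size, replace=False))
    return [str(b) for b in chosen]


def _score_unit(
    features: FeatureMatrix,
    labels: np.ndarray,
    params: PrioritizationParams,
    rng_tokens: tuple,
) -> np.ndarray:
    """One unit's AUC samples: repeated {subsample, select, classify}."""
    barcodes = np.asarray(features.barcodes, dtype=object)
    index = {b: i for i, b in enumerate(barcodes)}
    levels = sorted(set(labels))
    samples = np.empty(params.n_subsamples)
    for s in range(params.n_subsamples):
        rng = stable_rng(params.rng_seed, *rng_tokens, s)
        subset = subsample_balanced(barcodes, labels, params.subsample_size, rng)
        rows = np.array([index[b] for b in subset])
        X = features.values[rows, :]
        keep = select_variable_genes(
            FeatureMatrix(X, features.feature_ids, subset, kind=features.kind),
            params.var_quantile,
        )
        y = (np.asarray(labels, dtype=object)[rows] == levels[1]).astype(np.int64)
        samples[s] = rf_cv_auc(X[:, keep], y, params.n_folds, params.n_trees, rng)
    return samples


def prioritize_cell_types(
    features: FeatureMatrix,
    meta: ObservationMeta,
    comparison: tuple[str, str],
    params: PrioritizationParams | None = None,
) -> list[CellTypeScore]:
    """Score every cell type's condition separability for one comparison.

    Each cell type gets ``n_subsamples`` AUC samples from independent
    balanced subsamples; cell types with too few cells in either condition
    are marked skipped rather than silently dropped. RNG streams are derived
    per (cell type, subsample), so results for one cell type do not depend
    on which others are present.
    """
    params = params or PrioritizationParams()
    cond_a, cond_b = comparison
    table = meta.table.loc[[b for b in features.barcodes if b in meta.table.index]]
    if "cell_type" not in table:
        raise ValueError("metadata has no cell_type column")
    present = set(table["condition"].dropna().astype(str))
    for cond in comparison:
        if cond not in present:
            raise ValueError(f"condition {cond!r} absent from metadata")
    table = table[table["condition"].astype(str).isin([cond_a, cond_b])]
    table = table[table["cell_type"].notna()]

    position = {b: i for i, b in enumerate(features.barcodes)}
    scores: list[CellTypeScore] = []
    for cell_type in sorted(table["cell_type"].astype(str).unique()):
        rows = table[table["cell_type"].astype(str) == cell_type]
        labels = rows["condition"].astype(str).to_numpy()
        n_cells = {c: int((labels == c).sum()) for c in (cond_a, cond_b)}
        if min(n_cells.values()) < params.min_cells_per_condition:
            scores.append(
                CellTypeScore(
                    cell_type=cell_type,
                    mean_auc=float("nan"),
                    auc_samples=np.array([]),
                    n_cells=n_cells,
                    skipped=True,
                    reason="insufficient cells",
                )
            )
            continue
        sub = features.subset_barcodes(np.array([position[b] for b in rows.index]))
        samples = _score_unit(sub, labels, params, ("celltype", cell_type))
        scores.append(
            CellTypeScore(
                cell_type=cell_type,
                mean_auc=float(samples.mean()),
                auc_samples=samples,
                n_cells=n_cells,
            )
        )
    return scores


def scale_scores(
    scores_by_comparison: Mapping[str, Sequence[CellTypeScore]],
) -> pd.DataFrame:
    """Min-max scale mean AUCs within each comparison.

    Returns a cell-type x comparison frame with each column scaled to span
    [0, 1]; a degenerate (constant) column scales to all zeros. Skipped cell
    types appear as NaN.
    """
    if not scores_by_comparison:
        raise ValueError("need at least one comparison")
    columns = {}
    for name, scores in scores_by_comparison.items():
        columns[name] = pd.Series(
            {s.cell_type: s.mean_auc for s in scores if not s.skipped}, dtype=float
        )
    frame = pd.DataFrame(columns)
    scaled = frame.copy()
    for col in scaled:
        values = scaled[col]
        span = values.max() - values.min()
        scaled[col] = 0.0 if span == 0 or np.isnan(span) else (values - values.min()) / span
    return scaled
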