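"""Smoothing, evaluation and cross-method concordance for prioritization maps."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from ._forest import mann_whitney_auc

logger = logging.getLogger(__name__)

__all__ = [
    "SmoothedField",
    "RecoveryReport",
    "loess_smooth_2d",
    "concordance",
    "recovery_score",
]


@dataclass
class SmoothedField:
    grid_x: np.ndarray
    grid_y: np.ndarray
    values: np.ndarray  # shape (len(grid_y), len(grid_x))
    span: float


@dataclass
class RecoveryReport:
    pattern: str
    spearman_truth: float
    detection_auroc: float  # NaN when truth has a single class
    recovered: bool
    auroc_defined: bool


def loess_smooth_2d(
    coords: np.ndarray,
    values: np.ndarray,
    span: float = 0.3,
    grid_resolution: int = 50,
) -> SmoothedField:
    """Two-dimensional locally weighted (degree-1) regression on a grid.

    At each grid point the span-fraction nearest data points are fit with a
    plane under tricube distance weights. Degenerate windows (collinear or
    too few points) are widened with a warning; predictions are clipped to
    the input value range, as befits a local average. Exactly reproduces
    linear fields at interior grid points.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    if coords.shape != (n, 2):
        raise ValueError("coords must be (n, 2) matching values")
    if n < 10:
        raise ValueError("need at least 10 points to smooth")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    window = max(int(np.ceil(span * n)), 3)

    gx = np.linspace(coords[:, 0].min(), coords[:, 0].max(), grid_resolution)
    gy = np.linspace(coords[:, 1].min(), coords[:, 1].max(), grid_resolution)
    out = np.empty((grid_resolution, grid_resolution))
    lo, hi = values.min(), values.max()
    for j, y0 in enumerate(gy):
        for i, x0 in enumerate(gx):
            out[j, i] = _local_fit(coords, values, x0, y0, window)
    return SmoothedField(gx, gy, np.clip(out, lo, hi), span)


def _local_fit(coords, values, x0, y0, window) -> float:
    n = len(values)
    d = np.hypot(coords[:, 0] - x0, coords[:, 1] - y0)
    order = np.argsort(d)
    while True:
        sel = order[:window]
        dmax = d[sel[-1]]
        if dmax == 0:
            return float(values[sel].mean())
        w = (1 - np.clip(d[sel] / dmax, 0, 1) ** 3) ** 3
        w[w <= 0] = 1e-9  # keep boundary point from dropping out entirely
        X = np.column_stack([np.ones(len(sel)), coords[sel, 0] - x0, coords[sel, 1] - y0])
        wx = X * w[:, None]
        xtx = X.T @ wx
        if np.linalg.matrix_rank(xtx) == 3:
            beta = np.linalg.solve(xtx, wx.T @ values[sel])
            return float(beta[0])
        if window >= n:
            logger.warning("degenerate smoothing window at (%g, %g); using weighted mean", x0, y0)
            return float(np.average(values[sel], weights=w))
        window = min(n, int(np.ceil(window * 1.5)))
        logger.warning("collinear window at (%g, %g); widening to %d points", x0, y0, window)


def concordance(
    scores_a: pd.Series,
    scores_b: pd.Series,
    groups: pd.Series | None = None,
) -> dict:
    """Correlate two per-unit score vectors matched by index (e.g. barcode).

    Returns Pearson and Spearman correlations over matched pairs, plus — when
    group labels are supplied — the per-group mean of ``scores_b``
    (e.g. mean spatial AUC over the barcodes overlapping each cell type).
    Symmetric in the two score inputs for the correlation outputs.
    """
    matched = pd.concat([scores_a.rename("a"), scores_b.rename("b")], axis=1, join="inner")
    matched = matched.dropna()
    if len(matched) < 3:
        raise ValueError(f"need >= 3 matched pairs, got {len(matched)}")
    a, b = matched["a"].to_numpy(), matched["b"].to_numpy()
    result = {
        "n": len(matched),
        "pearson": float(pearsonr(a, b).statistic),
        "spearman": float(spearmanr(a, b).statistic),
    }
    if groups is not None:
        joined = matched.join(groups.rename("group"), how="inner")
        result["group_means"] = joined.groupby("group")["b"].mean().to_dict()
    return result


def recovery_score(
    auc_map,
    truth_intensity: pd.Series,
    positive_threshold: float = 0.5,
    spearman_min: float = 0.4,
    auroc_min: float = 0.8,
) -> RecoveryReport:
    """Judge whether an AUC map recovered the simulated perturbation region.

    ``spearman_truth`` correlates per-barcode mean AUC with true intensity;
    ``detection_auroc`` treats barcodes with truth above
    ``positive_threshold`` as positives. ``recovered`` requires both to
    clear their thresholds. With single-class truth (e.g. the null pattern)
    the AUROC is undefined and ``recovered`` is False.
    """
    if hasattr(auc_map, "__iter__") and not isinstance(auc_map, pd.Series):
        auc_map = pd.Series(
            {s.barcode: s.mean_auc for s in auc_map if not getattr(s, "skipped", False)}
        )
    matched = pd.concat(
        [auc_map.rename("auc"), truth_intensity.rename("truth")], axis=1, join="inner"
    ).dropna()
    if len(matched) != len(auc_map.dropna()):
        raise ValueError("truth intensity does not cover every scored barcode")
    auc = matched["auc"].to_numpy()
    truth = matched["truth"].to_numpy()
    positives = (truth > positive_threshold).astype(int)
    if np.ptp(truth) == 0:
        spear = float("nan")
    else:
        spear = float(spearmanr(auc, truth).statistic)
    if positives.min() == positives.max():
        return RecoveryReport("", spear, float("nan"), False, auroc_defined=False)
    auroc = mann_whitney_auc(positives, auc)
    recovered = bool(spear >= spearman_min and auroc >= auroc_min)
    return RecoveryReport("", spear, float(auroc), recovered, auroc_defined=True)
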