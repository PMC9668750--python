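"""Core data types, standard-format readers/writers, QC filters and
coordinate preprocessing for single-cell and spatial expression data.

Counts are stored dense (genes x observations, integer); the problem sizes
this package targets (thousands of genes by thousands of barcodes) fit
comfortably in memory and dense storage keeps the downstream classifier
paths simple.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "CountMatrix",
    "FeatureMatrix",
    "ObservationMeta",
    "SpatialCoordinates",
    "read_mtx_triplet",
    "read_dense_counts",
    "read_spatial_positions",
    "qc_filter_cells",
    "qc_filter_genes",
    "qc_filter_spatial_barcodes",
    "normalize_log1p_cpm",
    "mirror_x",
    "write_scores_table",
    "read_scores_table",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _dedupe(ids: Sequence[str], what: str) -> list[str]:
    """Make identifiers unique by suffixing duplicates with ``-1``, ``-2``, ..."""
    seen: dict[str, int] = {}
    out: list[str] = []
    n_dupes = 0
    for i in ids:
        i = str(i)
        if i in seen:
            seen[i] += 1
            out.append(f"{i}-{seen[i]}")
            n_dupes += 1
        else:
            seen[i] = 0
            out.append(i)
    if n_dupes:
        warnings.warn(f"{n_dupes} duplicate {what} identifiers made unique by suffixing")
    return out


@dataclass
class CountMatrix:
    """Genes x observations matrix of non-negative integer counts."""

    values: np.ndarray
    gene_ids: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("counts must be a 2D matrix")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(np.mod(self.values, 1) == 0):
                raise FormatError("count matrix contains non-integer entries")
            self.values = self.values.astype(np.int64)
        if self.values.size and self.values.min() < 0:
            raise ValueError("count matrix contains negative entries")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.barcodes = [str(b) for b in self.barcodes]
        if self.values.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} barcodes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            self.gene_ids = _dedupe(self.gene_ids, "gene")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_obs(self) -> int:
        return len(self.barcodes)

    def subset_barcodes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            self.values[:, keep],
            list(self.gene_ids),
            [self.barcodes[i] for i in keep],
        )

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            self.values[keep, :],
            [self.gene_ids[i] for i in keep],
            list(self.barcodes),
        )


@dataclass
class FeatureMatrix:
    """Observations x features matrix of finite reals fed to the classifiers.

    ``kind`` records provenance: log-normalized counts, an RNA-velocity
    matrix supplied in place of counts, or raw values.
    """

    values: np.ndarray
    feature_ids: list[str]
    barcodes: list[str]
    kind: str = "raw"

    _KINDS = ("log_normalized_counts", "velocity", "raw")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.barcodes = [str(b) for b in self.barcodes]
        if self.values.shape != (len(self.barcodes), len(self.feature_ids)):
            raise ValueError("feature matrix shape inconsistent with id lists")
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")

    @property
    def n_obs(self) -> int:
        return len(self.barcodes)

    def subset_barcodes(self, keep: np.ndarray) -> "FeatureMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return FeatureMatrix(
            self.values[keep, :],
            list(self.feature_ids),
            [self.barcodes[i] for i in keep],
            kind=self.kind,
        )


@dataclass
class ObservationMeta:
    """Per-observation metadata: condition, optional cell type, QC covariates.

    Backed by a DataFrame indexed by barcode. Recognized columns:
    ``condition``, ``cell_type``, ``section``, ``n_genes_detected``,
    ``mito_fraction``, ``n_umis``; extra columns pass through untouched.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate barcodes in observation metadata")
        self.table = self.table.copy()
        self.table.index = self.table.index.astype(str)
        if "mito_fraction" in self.table:
            mf = self.table["mito_fraction"].dropna()
            if len(mf) and ((mf < 0).any() or (mf > 1).any()):
                raise ValueError("mito_fraction must lie in [0, 1]")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, barcode_column: str = "barcode") -> "ObservationMeta":
        if barcode_column in frame.columns:
            frame = frame.set_index(barcode_column)
        return cls(frame)

    @property
    def barcodes(self) -> list[str]:
        return list(self.table.index)

    def subset(self, barcodes: Sequence[str]) -> "ObservationMeta":
        return ObservationMeta(self.table.loc[list(barcodes)])

    def condition_labels(self, barcodes: Sequence[str]) -> pd.Series:
        if "condition" not in self.table:
            raise ValueError("metadata has no condition column")
        sub = self.table.loc[list(barcodes), "condition"]
        if sub.isna().any():
            missing = list(sub.index[sub.isna()])[:5]
            raise ValueError(f"condition missing for barcodes {missing}")
        return sub


@dataclass
class SpatialCoordinates:
    """Per-barcode (x, y) in a common coordinate frame, plus section of origin."""

    table: pd.DataFrame  # index: barcode; columns: x, y, section

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate barcodes in coordinates")
        self.table = self.table.copy()
        self.table.index = self.table.index.astype(str)
        for col in ("x", "y"):
            if col not in self.table:
                raise ValueError(f"coordinates missing column {col!r}")
            self.table[col] = pd.to_numeric(self.table[col])
        if not np.all(np.isfinite(self.table[["x", "y"]].to_numpy())):
            raise ValueError("non-finite coordinates")
        if "section" not in self.table:
            self.table["section"] = ""

    @property
    def barcodes(self) -> list[str]:
        return list(self.table.index)

    def xy(self, barcodes: Sequence[str] | None = None) -> np.ndarray:
        t = self.table if barcodes is None else self.table.loc[list(barcodes)]
        return t[["x", "y"]].to_numpy(dtype=float)

    def subset(self, barcodes: Sequence[str]) -> "SpatialCoordinates":
        return SpatialCoordinates(self.table.loc[list(barcodes)])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_id_column(path: str | Path, column: int = 0) -> list[str]:
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if column >= frame.shape[1]:
        raise FormatError(f"{path}: expected at least {column + 1} columns")
    return frame.iloc[:, column].tolist()


def read_mtx_triplet(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    feature_id_column: int = 0,
) -> CountMatrix:
    """Read a Matrix Market triplet (matrix.mtx + features.tsv + barcodes.tsv).

    File ordering of genes and barcodes is preserved. Dimension mismatches
    raise :class:`FormatError` naming the offending file.
    """
    try:
        mat = mmread(str(matrix_path))
    except Exception as exc:  # scipy raises assorted ValueError subclasses
        raise FormatError(f"{matrix_path}: not a valid Matrix Market file ({exc})") from exc
    genes = _read_id_column(features_path, feature_id_column)
    barcodes = _read_id_column(barcodes_path)
    dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
    if dense.shape[0] != len(genes):
        raise FormatError(
            f"{features_path}: {len(genes)} features but matrix declares {dense.shape[0]} rows"
        )
    if dense.shape[1] != len(barcodes):
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix declares {dense.shape[1]} columns"
        )
    if not np.all(np.mod(dense, 1) == 0):
        raise FormatError(f"{matrix_path}: non-integer entries in count matrix")
    return CountMatrix(dense.astype(np.int64), genes, barcodes)


def read_dense_counts(path: str | Path) -> CountMatrix:
    """Read a dense TSV count table (rows = genes, header row = barcodes)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    values = frame.to_numpy()
    if not np.all(np.mod(values, 1) == 0):
        raise FormatError(f"{path}: non-integer entries in count table")
    return CountMatrix(values.astype(np.int64), frame.index.tolist(), frame.columns.tolist())


def write_mtx_triplet(counts: CountMatrix, out_dir: str | Path) -> None:
    """Write matrix.mtx + features.tsv + barcodes.tsv into ``out_dir``."""
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(str(out / "matrix.mtx"), coo_matrix(counts.values))
    pd.Series(counts.gene_ids).to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(counts.barcodes).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)


def read_spatial_positions(
    path: str | Path,
    counts: CountMatrix | None = None,
) -> tuple[SpatialCoordinates, pd.Series]:
    """Read a positions table with columns barcode, x, y, section, condition.

    Returns coordinates plus the per-barcode condition labels. When a count
    matrix is supplied, positions for barcodes absent from it are reported
    and dropped.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tsv.gz", ".txt")) else None
    frame = pd.read_csv(path, sep=sep, engine="python")
    required = {"barcode", "x", "y", "condition"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if frame["barcode"].duplicated().any():
        dupes = frame.loc[frame["barcode"].duplicated(), "barcode"].tolist()[:5]
        raise FormatError(f"{path}: duplicated barcodes {dupes}")
    if frame[["x", "y"]].isna().any().any():
        raise FormatError(f"{path}: missing coordinate values")
    if "section" not in frame.columns:
        frame["section"] = ""
    frame = frame.set_index("barcode")
    frame.index = frame.index.astype(str)
    if counts is not None:
        known = set(counts.barcodes)
        unknown = [b for b in frame.index if b not in known]
        if unknown:
            logger.warning(
                "%d positioned barcodes absent from count matrix; dropped (e.g. %s)",
                len(unknown),
                unknown[:3],
            )
            frame = frame.drop(index=unknown)
    coords = SpatialCoordinates(frame[["x", "y", "section"]])
    return coords, frame["condition"].astype(str)


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def _genes_detected(counts: CountMatrix) -> np.ndarray:
    return (counts.values > 0).sum(axis=0)


def _mito_fraction(counts: CountMatrix, mito_prefix: str) -> np.ndarray:
    is_mito = np.array([g.lower().startswith(mito_prefix.lower()) for g in counts.gene_ids])
    totals = counts.values.sum(axis=0).astype(float)
    totals[totals == 0] = np.nan
    frac = counts.values[is_mito, :].sum(axis=0) / totals
    return np.nan_to_num(frac, nan=0.0)


def qc_filter_cells(
    counts: CountMatrix,
    meta: ObservationMeta,
    min_genes: int = 200,
    max_mito: float = 0.05,
    mito_prefix: str = "mt-",
) -> tuple[CountMatrix, ObservationMeta]:
    """Drop cells expressing fewer than ``min_genes`` genes or with more than
    ``max_mito`` mitochondrial fraction. Boundary values are retained (the
    inequalities are strict). Covariates come from ``meta`` when present,
    otherwise they are computed from the counts.
    """
    missing = [b for b in counts.barcodes if b not in meta.table.index]
    if missing:
        raise ValueError(f"metadata missing for barcodes {missing[:5]}")
    sub = meta.table.loc[counts.barcodes]
    if "n_genes_detected" in sub and sub["n_genes_detected"].notna().all():
        n_genes = sub["n_genes_detected"].to_numpy(dtype=float)
    else:
        n_genes = _genes_detected(counts)
    if "mito_fraction" in sub and sub["mito_fraction"].notna().all():
        mito = sub["mito_fraction"].to_numpy(dtype=float)
    else:
        mito = _mito_fraction(counts, mito_prefix)
    keep = (n_genes >= min_genes) & (mito <= max_mito)
    if not keep.any():
        warnings.warn("QC filter removed every cell")
    filtered = counts.subset_barcodes(keep)
    return filtered, meta.subset(filtered.barcodes)


def qc_filter_genes(counts: CountMatrix, min_observations: int = 3) -> CountMatrix:
    """Keep genes detected (non-zero) in at least ``min_observations`` columns."""
    detected_in = (counts.values > 0).sum(axis=1)
    return counts.subset_genes(detected_in >= min_observations)


def qc_filter_spatial_barcodes(counts: CountMatrix, min_umis: int = 5000) -> CountMatrix:
    """Keep barcodes whose total UMI count is at least ``min_umis``."""
    totals = counts.values.sum(axis=0)
    return counts.subset_barcodes(totals >= min_umis)


# ---------------------------------------------------------------------------
# Normalization and coordinate preprocessing
# ---------------------------------------------------------------------------

def normalize_log1p_cpm(counts: CountMatrix, scale: float = 1e4) -> FeatureMatrix:
    """Counts-per-``scale`` log1p normalization: log(1 + scale * c / colsum).

    Returns an observations x features matrix ready for classification.
    """
    totals = counts.values.sum(axis=0).astype(float)
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        raise ValueError(f"zero-sum columns for barcodes {[counts.barcodes[i] for i in zero[:5]]}")
    normed = np.log1p(scale * counts.values / totals[np.newaxis, :])
    return FeatureMatrix(
        normed.T, list(counts.gene_ids), list(counts.barcodes), kind="log_normalized_counts"
    )


def mirror_x(coords: SpatialCoordinates) -> SpatialCoordinates:
    """Replace each x coordinate with its absolute value (left-right folding)."""
    table = coords.table.copy()
    table["x"] = table["x"].abs()
    return SpatialCoordinates(table)


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

def write_scores_table(scores, path: str | Path) -> None:
    """Write prioritization scores as TSV: unit_id, mean_auc, n_repeats, sd_auc.

    Accepts any iterable of objects exposing a unit identifier (``cell_type``
    or ``barcode``), ``mean_auc`` and ``auc_samples``. Values round-trip
    losslessly at 6 decimals.
    """
    rows = []
    for s in scores:
        unit = getattr(s, "cell_type", None) or getattr(s, "barcode", None)
        samples = np.asarray(s.auc_samples, dtype=float)
        rows.append(
            {
                "unit_id": unit,
                "mean_auc": round(float(s.mean_auc), 6) if not np.isnan(s.mean_auc) else np.nan,
                "n_repeats": len(samples),
                "sd_auc": round(float(samples.std(ddof=0)), 6) if len(samples) else np.nan,
            }
        )
    frame = pd.DataFrame(rows, columns=["unit_id", "mean_auc", "n_repeats", "sd_auc"])
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_scores_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
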