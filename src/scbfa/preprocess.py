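"""Count-matrix I/O, quality control, normalization, gene selection, and
technical-noise diagnostics.

QC filter order and defaults: cells with > 50% mitochondrial counts are
removed first, then genes detected in < 1% of remaining cells, then cells
whose library size falls strictly below the 1/8 quantile (linear-interpolation
quantile) of the remaining cells' library sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data import CountMatrix, DetectionMatrix, ValidationError

MITO_PREFIXES = ("MT-", "mt-", "Mt-")


class FormatError(ValueError):
    """Malformed input file."""


class EmptyAfterQCError(ValueError):
    """Every cell (or every gene) was removed by the QC filters."""


@dataclass
class QcParams:
    """Thresholds for :func:`qc_filter`. All fractions lie in (0, 1]."""

    mito_fraction_max: float = 0.50
    min_cell_fraction_per_gene: float = 0.01
    library_quantile_min: float = 0.125

    def __post_init__(self) -> None:
        for name in (
            "mito_fraction_max",
            "min_cell_fraction_per_gene",
            "library_quantile_min",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class QcReport:
    """Provenance of a QC run: ids removed at each step."""

    cells_removed_mito: list = field(default_factory=list)
    genes_removed_low_detection: list = field(default_factory=list)
    cells_removed_library: list = field(default_factory=list)
    params: QcParams = field(default_factory=QcParams)

    def to_dict(self) -> dict:
        return {
            "cells_removed_mito": list(map(str, self.cells_removed_mito)),
            "genes_removed_low_detection": list(
                map(str, self.genes_removed_low_detection)
            ),
            "cells_removed_library": list(map(str, self.cells_removed_library)),
            "params": {
                "mito_fraction_max": self.params.mito_fraction_max,
                "min_cell_fraction_per_gene": self.params.min_cell_fraction_per_gene,
                "library_quantile_min": self.params.library_quantile_min,
            },
        }


@dataclass
class DispersionProfile:
    """Per-gene mean/dispersion estimates and a smoothed mean->dispersion trend.

    Means are counts-per-million (no length correction: UMI-style data has no
    length bias). Dispersions are method-of-moments NB estimates on
    size-factor-normalized counts. The trend is a local linear regression fit
    after trimming ``trimmed_fraction`` of genes from each tail of the mean
    distribution.
    """

    gene_mean_tpm: np.ndarray
    gene_dispersion: np.ndarray
    trend: Callable[[np.ndarray], np.ndarray]
    trimmed_fraction: float = 0.025

    def median_trend_dispersion(self) -> float:
        lo = np.quantile(self.gene_mean_tpm, self.trimmed_fraction)
        hi = np.quantile(self.gene_mean_tpm, 1 - self.trimmed_fraction)
        kept = self.gene_mean_tpm[
            (self.gene_mean_tpm >= lo) & (self.gene_mean_tpm <= hi)
        ]
        return float(np.median(self.trend(kept)))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def mito_mask_from_ids(feature_ids, prefixes=MITO_PREFIXES) -> np.ndarray:
    """Flag features whose id starts with a mitochondrial prefix ('MT-'/'mt-')."""
    return np.array([str(f).startswith(prefixes) for f in feature_ids], dtype=bool)


def _read_lines(path: Path) -> np.ndarray:
    with open(path) as fh:
        # barcodes/features sidecars may be TSV; the id is the first column
        return np.array([line.rstrip("\n").split("\t")[0] for line in fh if line.strip()],
                        dtype=object)


def _mtx_sidecars(path: Path) -> tuple[Path, Path]:
    """Locate barcode/feature sidecars for an .mtx file or a 10x-style directory."""
    if path.is_dir():
        mtx = path / "matrix.mtx"
        barcodes = path / "barcodes.tsv"
        features = path / "features.tsv"
        if not features.exists():
            features = path / "genes.tsv"
        if not (mtx.exists() and barcodes.exists() and features.exists()):
            raise FormatError(
                f"directory {path} must contain matrix.mtx, barcodes.tsv and "
                "features.tsv (or genes.tsv)"
            )
        return mtx, barcodes, features  # type: ignore[return-value]
    stem = path.with_suffix("")
    barcodes = Path(str(stem) + ".barcodes.txt")
    features = Path(str(stem) + ".features.txt")
    if not (barcodes.exists() and features.exists()):
        raise FormatError(
            f"missing sidecars for {path}: expected {barcodes} and {features}"
        )
    return path, barcodes, features  # type: ignore[return-value]


def read_counts(
    path,
    format: str = "mtx",
    orientation: str = "cells_by_features",
    mito_prefixes=MITO_PREFIXES,
) -> CountMatrix:
    """Read a count matrix from disk into the canonical cells x features layout.

    Parameters
    ----------
    path
        For ``format='mtx'``: either a MatrixMarket file with
        ``<stem>.barcodes.txt`` / ``<stem>.features.txt`` sidecars, or a
        10x-style directory (``matrix.mtx`` + ``barcodes.tsv`` +
        ``features.tsv``/``genes.tsv``).
        For ``format='delimited'``: a CSV/TSV file with a header row and a
        first id column (delimiter sniffed from the extension).
    orientation
        Layout of the file on disk; ``features_by_cells`` inputs are
        transposed on read.
    """
    path = Path(path)
    if orientation not in ("cells_by_features", "features_by_cells"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    if format == "mtx":
        mtx, barcodes, features = _mtx_sidecars(path)
        try:
            mat = scipy.io.mmread(mtx)
        except ValueError as exc:
            raise FormatError(f"malformed MatrixMarket file {mtx}: {exc}") from exc
        values = np.asarray(
            mat.toarray() if scipy.sparse.issparse(mat) else mat
        )
        cell_ids = _read_lines(barcodes)
        feature_ids = _read_lines(features)
        if orientation == "features_by_cells":
            values = values.T
    elif format == "delimited":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(header) != len(set(header)):
            dup = next(h for h in header if header.count(h) > 1)
            raise ValidationError(f"duplicate feature id in header: {dup!r}")
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise FormatError(f"malformed delimited file {path}: {exc}") from exc
        if df.shape[1] == 0:
            raise FormatError(f"{path}: no data columns (wrong delimiter?)")
        if orientation == "features_by_cells":
            df = df.T
        values = df.to_numpy()
        cell_ids = np.asarray(df.index, dtype=object)
        feature_ids = np.asarray(df.columns, dtype=object)
    else:
        raise ValueError(f"unknown format {format!r}")

    return CountMatrix(
        values=values,
        cell_ids=cell_ids,
        feature_ids=feature_ids,
        feature_is_mito=mito_mask_from_ids(feature_ids, mito_prefixes),
    )


def write_counts(counts: CountMatrix, path, format: str = "mtx") -> None:
    """Write a count matrix in MTX (with sidecars) or delimited form."""
    path = Path(path)
    if format == "mtx":
        path.parent.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(counts.values))
        stem = path.with_suffix("")
        Path(str(stem) + ".barcodes.txt").write_text(
            "\n".join(map(str, counts.cell_ids)) + "\n"
        )
        Path(str(stem) + ".features.txt").write_text(
            "\n".join(map(str, counts.feature_ids)) + "\n"
        )
    elif format == "delimited":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        pd.DataFrame(
            counts.values, index=counts.cell_ids, columns=counts.feature_ids
        ).to_csv(path, sep=sep)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_qc_report(report: QcReport, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# QC / binarization / normalization
# ---------------------------------------------------------------------------


def qc_filter(
    counts: CountMatrix, params: QcParams | None = None
) -> tuple[CountMatrix, QcReport]:
    """Apply the three-step QC filter; returns the filtered matrix + provenance.

    Steps, in order: (1) drop cells whose mitochondrial count fraction exceeds
    ``mito_fraction_max``; (2) drop genes detected in fewer than
    ``min_cell_fraction_per_gene`` of the remaining cells; (3) drop cells with
    library size strictly below the ``library_quantile_min`` quantile
    (linear-interpolation definition) of the remaining cells' library sizes.
    """
    params = params or QcParams()
    report = QcReport(params=params)

    lib = counts.library_sizes().astype(float)
    mito_counts = counts.values[:, counts.feature_is_mito].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(lib > 0, mito_counts / np.maximum(lib, 1), 0.0)
    keep_cells = mito_frac <= params.mito_fraction_max
    report.cells_removed_mito = list(counts.cell_ids[~keep_cells])
    if not keep_cells.any():
        raise EmptyAfterQCError("empty after QC: all cells failed the mito filter")
    current = counts.subset(cells=np.where(keep_cells)[0])

    detected_frac = (current.values >= 1).mean(axis=0)
    keep_genes = detected_frac >= params.min_cell_fraction_per_gene
    report.genes_removed_low_detection = list(current.feature_ids[~keep_genes])
    if not keep_genes.any():
        raise EmptyAfterQCError("empty after QC: all genes failed the detection filter")
    current = current.subset(features=np.where(keep_genes)[0])

    lib = current.library_sizes().astype(float)
    threshold = np.quantile(lib, params.library_quantile_min)
    keep_cells = lib >= threshold
    report.cells_removed_library = list(current.cell_ids[~keep_cells])
    if not keep_cells.any():
        raise EmptyAfterQCError("empty after QC: all cells failed the library filter")
    current = current.subset(cells=np.where(keep_cells)[0])

    return current, report


def binarize(counts: CountMatrix | DetectionMatrix) -> DetectionMatrix:
    """Detection pattern B: B_ij = 1 iff O_ij >= 1. Idempotent."""
    if isinstance(counts, DetectionMatrix):
        return counts
    return DetectionMatrix(
        values=(counts.values >= 1).astype(np.int8),
        cell_ids=counts.cell_ids,
        feature_ids=counts.feature_ids,
    )


def normalize_log_library(counts: CountMatrix, mode: str = "scrna") -> np.ndarray:
    """Log-normalize counts.

    ``scrna``: log(O_ij / c_i + 1) with c_i the cell library size (natural log).
    ``scatac``: log(O_ij + 1), no library scaling.
    """
    if mode == "scrna":
        lib = counts.library_sizes().astype(float)
        if np.any(lib == 0):
            bad = list(map(str, counts.cell_ids[lib == 0]))
            raise ValueError(f"zero library size for cells: {bad}")
        return np.log1p(counts.values / lib[:, None])
    if mode == "scatac":
        return np.log1p(counts.values.astype(float))
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Gene selection
# ---------------------------------------------------------------------------


def _top_by_score(scores: np.ndarray, feature_ids: np.ndarray, n: int) -> np.ndarray:
    # descending score, ties broken by lexicographic feature id
    order = sorted(
        range(len(scores)), key=lambda j: (-scores[j], str(feature_ids[j]))
    )
    return np.array(order[:n], dtype=int)


def select_heg(counts: CountMatrix, n_genes: int = 2000) -> np.ndarray:
    """Indices of the ``n_genes`` features with largest raw-count variance."""
    if n_genes > counts.n_features:
        raise ValueError(f"n_genes={n_genes} exceeds {counts.n_features} features")
    var = counts.values.var(axis=0, ddof=1) if counts.n_cells > 1 else np.zeros(
        counts.n_features
    )
    return _top_by_score(var, counts.feature_ids, n_genes)


def select_hvg(counts: CountMatrix, n_genes: int = 2000) -> np.ndarray:
    """Indices of the most overdispersed genes (standardized-variance ranking).

    A mean-variance trend is fit on log10 scale by local regression across
    genes; each gene's counts are standardized using the trend-expected
    standard deviation, clipped at sqrt(N), and the variance of the clipped
    values is the ranking score. Deterministic given the data; rankings may
    differ from external HVG tools.
    """
    if n_genes > counts.n_features:
        raise ValueError(f"n_genes={n_genes} exceeds {counts.n_features} features")
    X = counts.values.astype(float)
    n = counts.n_cells
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)

    not_const = var > 0
    if len(np.unique(mean[not_const])) < 3:
        raise ValueError("fewer than 3 distinct gene means: trend unfittable")

    log_mean = np.log10(mean[not_const])
    log_var = np.log10(var[not_const])
    fitted = lowess(
        log_var, log_mean, frac=0.3, it=2, return_sorted=False
    )
    # lowess can return NaN for isolated x; fall back to the raw variance there
    fitted = np.where(np.isfinite(fitted), fitted, log_var)
    expected_sd = np.sqrt(10.0 ** fitted)

    score = np.zeros(counts.n_features)
    clip = np.sqrt(n)
    idx = np.where(not_const)[0]
    for pos, j in enumerate(idx):
        z = (X[:, j] - mean[j]) / expected_sd[pos]
        z = np.clip(z, -clip, clip)
        score[j] = float(np.sum((z - z.mean()) ** 2) / (n - 1)) if n > 1 else 0.0
    return _top_by_score(score, counts.feature_ids, n_genes)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def gene_detection_rate(B: DetectionMatrix) -> float:
    """Grand mean of the detection matrix: fraction of detected (cell, gene) pairs."""
    return float(B.values.mean())


def detection_rate_marginals(B: DetectionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell and per-gene detection fractions (both average to the GDR)."""
    return B.values.mean(axis=1), B.values.mean(axis=0)


def dispersion_trend(counts: CountMatrix) -> DispersionProfile:
    """Per-gene NB dispersion estimates plus a local-regression trend on gene mean.

    Dispersion alpha_j is estimated by method of moments on size-factor
    normalized counts (library size / mean library size), alpha_j =
    max(0, (s2_j - m_j) / m_j^2). Genes in the top/bottom 2.5% by mean are
    trimmed before fitting the trend to avoid boundary artifacts.
    """
    if counts.n_features < 20:
        raise ValueError("need at least 20 genes to fit a dispersion trend")
    lib = counts.library_sizes().astype(float)
    if np.any(lib == 0):
        raise ValueError("zero library size; run qc_filter first")
    cpm = counts.values / lib[:, None] * 1e6
    gene_mean_tpm = cpm.mean(axis=0)
    if len(np.unique(gene_mean_tpm)) < 2:
        raise ValueError("degenerate input: all genes have identical mean")

    sf = lib / lib.mean()
    norm = counts.values / sf[:, None]
    m = norm.mean(axis=0)
    s2 = norm.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(m > 0, np.maximum(0.0, (s2 - m) / np.maximum(m, 1e-300) ** 2), 0.0)

    lo = np.quantile(gene_mean_tpm, 0.025)
    hi = np.quantile(gene_mean_tpm, 0.975)
    kept = (gene_mean_tpm >= lo) & (gene_mean_tpm <= hi)
    x = np.log10(np.maximum(gene_mean_tpm[kept], 1e-12))
    y = alpha[kept]
    smoothed = lowess(y, x, frac=0.5, it=2, return_sorted=True)
    xs, ys = smoothed[:, 0], smoothed[:, 1]
    xs, uniq = np.unique(xs, return_index=True)
    ys = ys[uniq]

    def trend(mean_tpm: np.ndarray) -> np.ndarray:
        q = np.log10(np.maximum(np.atleast_1d(np.asarray(mean_tpm, dtype=float)), 1e-12))
        return np.interp(q, xs, ys)

    return DispersionProfile(
        gene_mean_tpm=gene_mean_tpm, gene_dispersion=alpha, trend=trend
    )


GDR_RECOMMEND_THRESHOLD = 0.90


def diagnose(counts: CountMatrix) -> dict:
    """Recommend the detection model when the gene detection rate is below 90%.

    Returns a record with the GDR, a dispersion summary (median trend
    dispersion, or None when a trend cannot be fit), and the recommendation
    (strict inequality at the 0.90 boundary).
    """
    B = binarize(counts)
    gdr = gene_detection_rate(B)
    try:
        profile = dispersion_trend(counts)
        summary = profile.median_trend_dispersion()
    except ValueError:
        summary = None
    return {
        "gdr": gdr,
        "dispersion_summary": summary,
        "recommend_detection_model": bool(gdr < GDR_RECOMMEND_THRESHOLD),
    }
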