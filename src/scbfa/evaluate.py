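"""Benchmark metrics: repeated cross-validated MCC, AWSS, marker-gene AUROC,
hierarchical-clustering NMI/ARI, and the plug-in batch-correction scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    adjusted_rand_score,
    confusion_matrix,
    normalized_mutual_info_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .data import DetectionMatrix
from .model import CovariateDesign, ScbfaFit, ScbfaHyper, fit_scbfa

# "non-regularized" logistic classifier: a negligible ridge (1e-6, i.e.
# C = 1e6) plus an iteration cap guarantees termination on separable embeddings
_LOGISTIC_C = 1e6
_LOGISTIC_MAX_ITER = 500


@dataclass
class EvalReport:
    """Benchmark surfaces for one embedding/loading matrix."""

    mcc_per_repeat: list[float] = field(default_factory=list)
    mcc_mean: float | None = None
    awss: float | None = None
    auroc_per_factor: list[float] | None = None
    nmi: float | None = None
    ari: float | None = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mcc_per_repeat": self.mcc_per_repeat,
            "mcc_mean": self.mcc_mean,
            "awss": self.awss,
            "auroc_per_factor": self.auroc_per_factor,
            "nmi": self.nmi,
            "ari": self.ari,
            "config": self.config,
        }


@dataclass
class MarkerSet:
    """A non-empty set of marker feature ids with a provenance label."""

    marker_ids: set
    source_label: str = ""

    def __post_init__(self) -> None:
        self.marker_ids = set(map(str, self.marker_ids))
        if not self.marker_ids:
            raise ValueError("marker set is empty")


def mcc_from_confusion(confusion: np.ndarray) -> float:
    """Matthews correlation coefficient of a confusion matrix (true x predicted).

    The 2x2 case reduces to (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN));
    larger matrices use the Gorodkin multiclass generalization. A zero
    denominator returns 0.
    """
    C = np.asarray(confusion, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(C < 0):
        raise ValueError("confusion matrix entries must be nonnegative")
    s = C.sum()
    if (C.sum(axis=1) > 0).sum() < 2:
        raise ValueError("need at least two classes with nonzero totals")
    c = np.trace(C)
    t = C.sum(axis=1)  # true-class totals
    p = C.sum(axis=0)  # predicted-class totals
    num = c * s - t @ p
    den = np.sqrt(s**2 - p @ p) * np.sqrt(s**2 - t @ t)
    if den == 0:
        return 0.0
    return float(num / den)


def crossval_mcc(
    Z: np.ndarray,
    labels,
    folds: int = 5,
    repeats: int = 15,
    seed: int = 0,
) -> EvalReport:
    """Repeated stratified k-fold MCC of a multinomial logistic classifier.

    Per repeat, the test-fold predictions of all folds are pooled into a
    single confusion matrix whose MCC is recorded; the report's headline
    number is the mean over repeats.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    counts = np.bincount(y)
    if counts.min() < folds:
        small = classes[np.argmin(counts)]
        raise ValueError(
            f"class {small!r} has {counts.min()} members, fewer than {folds} folds"
        )
    rng = np.random.default_rng(seed)
    mccs = []
    for _ in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        y_pred = np.empty_like(y)
        for train, test in skf.split(Z, y):
            clf = LogisticRegression(
                C=_LOGISTIC_C, max_iter=_LOGISTIC_MAX_ITER, solver="lbfgs"
            )
            clf.fit(Z[train], y[train])
            y_pred[test] = clf.predict(Z[test])
        cm = confusion_matrix(y, y_pred, labels=np.arange(len(classes)))
        mccs.append(mcc_from_confusion(cm))
    return EvalReport(
        mcc_per_repeat=mccs,
        mcc_mean=float(np.mean(mccs)),
        config={"folds": folds, "repeats": repeats, "seed": seed, "K": Z.shape[1]},
    )


def awss(Z: np.ndarray) -> float:
    """Averaged within-group sum of squares: trace(W'W)/(N-1) with W = Z - Zbar.

    Equals the sum of per-column sample variances.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    n = Z.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows")
    W = Z - Z.mean(axis=0)
    return float(np.trace(W.T @ W) / (n - 1))


def homogeneity_awss(Z: np.ndarray) -> float:
    """AWSS of an embedding rescaled to unit median centered row norm.

    Raw AWSS is unit-dependent, so embeddings produced by different methods
    are not directly comparable. Centering and dividing by the median row
    norm fixes the typical spread at 1, making the statistic a measure of
    excess (tail) spread: homogeneous technical replicates score low, while
    embeddings dominated by a few noisy cells score high.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    Zc = Z - Z.mean(axis=0)
    med = np.median(np.linalg.norm(Zc, axis=1))
    if med == 0:
        return 0.0
    return awss(Zc / med)


def marker_auroc(A: np.ndarray, feature_ids, markers: MarkerSet) -> np.ndarray:
    """Per-factor AUROC of marker membership against |loading| rank.

    Ties are handled by midrank (so an all-tied factor scores exactly 0.5).
    """
    A = np.asarray(A, dtype=float)
    feature_ids = np.asarray([str(f) for f in feature_ids], dtype=object)
    if A.ndim != 2 or A.shape[1] != len(feature_ids):
        raise ValueError("loadings must be K x G with one id per feature")
    is_marker = np.array([f in markers.marker_ids for f in feature_ids], dtype=bool)
    if not is_marker.any():
        raise ValueError("no marker ids intersect the analyzed features")
    if is_marker.all():
        raise ValueError("every analyzed feature is a marker; AUROC undefined")
    out = np.empty(A.shape[0])
    for k in range(A.shape[0]):
        scores = np.abs(A[k])
        if np.all(scores == scores[0]):
            out[k] = 0.5  # total tie: midrank convention
        else:
            out[k] = roc_auc_score(is_marker, scores)
    return out


def cluster_score(
    Z: np.ndarray, labels, n_clusters: int | None = None
) -> tuple[float, float]:
    """Ward-linkage hierarchical clustering of the embedding, scored by NMI
    (square-root normalization) and ARI against the given labels."""
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels)
    if n_clusters is None:
        n_clusters = len(np.unique(labels))
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    if n_clusters > Z.shape[0]:
        raise ValueError("more clusters than cells")
    pred = AgglomerativeClustering(
        n_clusters=n_clusters, linkage="ward"
    ).fit_predict(Z)
    nmi = float(normalized_mutual_info_score(labels, pred, average_method="geometric"))
    ari = float(adjusted_rand_score(labels, pred))
    return nmi, ari


def common_celltype_subset(labels, batches) -> np.ndarray:
    """Boolean mask of cells whose type is represented in every batch."""
    labels = np.asarray(labels)
    batches = np.asarray(batches)
    all_batches = set(np.unique(batches))
    common = {
        t for t in np.unique(labels)
        if set(np.unique(batches[labels == t])) == all_batches
    }
    return np.isin(labels, list(common))


def batch_plugin_fit(
    B: DetectionMatrix,
    X: CovariateDesign,
    labels,
    batches,
    hyper: ScbfaHyper | None = None,
) -> ScbfaFit:
    """Two-stage batch correction for designs confounded with cell type.

    Stage 1 fits the model on the largest subset of cell types represented in
    all batches to estimate the covariate coefficients beta. Stage 2 refits on
    the full data with beta frozen at that plug-in estimate, re-estimating
    Z, A, u and v.
    """
    mask = common_celltype_subset(labels, batches)
    if not mask.any():
        raise ValueError(
            "no cell type is present in every batch; use the direct-covariate "
            "path (pass X to fit_scbfa) instead"
        )
    idx = np.where(mask)[0]
    sub_vals = B.values[idx]
    # features degenerate within the subset carry no batch information there;
    # their coefficients stay at the penalized default of 0
    col = sub_vals.mean(axis=0)
    informative = np.where((col > 0) & (col < 1))[0]
    B_sub = DetectionMatrix(
        values=sub_vals[:, informative],
        cell_ids=B.cell_ids[idx],
        feature_ids=B.feature_ids[informative],
    )
    X_sub = CovariateDesign(
        X=X.X[idx], column_names=X.column_names, standardized=X.standardized,
        means=X.means, scales=X.scales,
    )
    hyper = hyper or ScbfaHyper()
    stage1 = fit_scbfa(B_sub, X=X_sub, hyper=hyper)
    beta_hat = np.zeros((X.X.shape[1], B.n_features))
    beta_hat[:, informative] = stage1.beta
    return fit_scbfa(B, X=X, hyper=hyper, fixed_beta=beta_hat)


def batch_residual_pca(
    M: np.ndarray,
    X: CovariateDesign,
    labels,
    batches,
    K: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear-residual analog of the plug-in scheme for the PCA path.

    beta is estimated by least squares of the observation matrix on the
    covariates within the common-cell-type subset; the full matrix is then
    residualized with that beta and decomposed by (centered, unscaled) PCA.
    Returns ``(embeddings, loadings, explained_variance)``.
    """
    M = np.asarray(M, dtype=float)
    mask = common_celltype_subset(labels, batches)
    if not mask.any():
        raise ValueError("no cell type is present in every batch")
    beta_hat, *_ = np.linalg.lstsq(X.X[mask], M[mask], rcond=None)
    R = M - X.X @ beta_hat
    n = R.shape[0]
    centered = R - R.mean(axis=0)
    U, d, Vt = np.linalg.svd(centered, full_matrices=False)
    return U[:, :K] * d[:K], Vt[:K], d[:K] ** 2 / (n - 1)
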