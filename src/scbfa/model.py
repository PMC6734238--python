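"""Penalized Bernoulli factor model of detection patterns, and the Binary PCA
fast path.

The model explains the binary detection matrix B through
``logit(mu_ij) = x_i' beta_j + z_i' a_j + u_i + v_j`` and maximizes

    sum_ij [B_ij log mu_ij + (1 - B_ij) log(1 - mu_ij)]
        - eps1 ||A||_F^2 - eps2 ||Z||_F^2 - eps3 ||beta||_F^2

over all parameters jointly with a quasi-Newton (L-BFGS-B) routine. Defaults:
eps0 = max(N, G), eps1 = eps3 = eps0 / G, eps2 = eps0 / N. After convergence
Z and A are rebalanced by an SVD split of their product so that factors are
orthogonal and ||Z||_F = ||A||_F.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
from scipy.special import expit as _sigmoid
from scipy.special import logit as _logit

from .data import DetectionMatrix

LOGIT_CLIP = 30.0  # prevents overflow/log(0) with unpenalized intercepts
_INIT_RATE_CLIP = 1e-3  # detection rates clipped into [1e-3, 1-1e-3] for warm start


@dataclass
class ScbfaHyper:
    """Hyperparameters of the detection factor model.

    ``eps0``/``eps1``/``eps2``/``eps3`` default to the data-dependent values
    above when left as None; they are resolved against the dimensions of the
    matrix actually being fit (post-filter, post-gene-selection).
    """

    K: int = 10
    eps0: float | None = None
    eps1: float | None = None
    eps2: float | None = None
    eps3: float | None = None
    max_iter: int = 500
    tol: float = 1e-8
    seed: int = 0

    def resolve(self, n_cells: int, n_features: int) -> "ScbfaHyper":
        eps0 = float(max(n_cells, n_features)) if self.eps0 is None else self.eps0
        eps1 = eps0 / n_features if self.eps1 is None else self.eps1
        eps2 = eps0 / n_cells if self.eps2 is None else self.eps2
        eps3 = eps0 / n_features if self.eps3 is None else self.eps3
        if min(eps1, eps2, eps3) < 0:
            raise ValueError("penalties must be nonnegative")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        return ScbfaHyper(
            K=self.K, eps0=eps0, eps1=eps1, eps2=eps2, eps3=eps3,
            max_iter=self.max_iter, tol=self.tol, seed=self.seed,
        )


@dataclass
class CovariateDesign:
    """Standardized N x C cell-level covariate matrix."""

    X: np.ndarray
    column_names: list[str]
    standardized: bool
    means: np.ndarray | None = None
    scales: np.ndarray | None = None

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        """Apply the stored centering/scaling to new rows (e.g. a cell subset)."""
        if not self.standardized:
            return np.asarray(X_new, dtype=float)
        return (np.asarray(X_new, dtype=float) - self.means) / self.scales


def standardize_covariates(X, column_names=None) -> CovariateDesign:
    """Z-score each covariate column (population standard deviation).

    Stores the means and scales so the same affine map can be reused on cell
    subsets. Constant columns are rejected.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise ValueError("X must be 2-d")
    if column_names is None:
        column_names = [f"cov{j}" for j in range(X.shape[1])]
    means = X.mean(axis=0)
    scales = X.std(axis=0)  # population sd (ddof=0)
    for j, s in enumerate(scales):
        if s == 0:
            raise ValueError(f"constant covariate column: {column_names[j]!r}")
    return CovariateDesign(
        X=(X - means) / scales,
        column_names=list(column_names),
        standardized=True,
        means=means,
        scales=scales,
    )


@dataclass
class ScbfaFit:
    """Fitted detection factor model parameters."""

    Z: np.ndarray            # N x K cell embeddings
    A: np.ndarray            # K x G loadings
    beta: np.ndarray         # C x G covariate coefficients (C may be 0)
    u: np.ndarray            # N cell intercepts
    v: np.ndarray            # G gene intercepts
    hyper: ScbfaHyper | None = None
    objective_trace: list = field(default_factory=list)
    converged: bool = False

    def linear_predictor(self, X: np.ndarray | None = None) -> np.ndarray:
        eta = self.Z @ self.A + self.u[:, None] + self.v[None, :]
        if self.beta.size and X is not None:
            eta = eta + X @ self.beta
        return eta

    def predicted_mu(self, X: np.ndarray | None = None) -> np.ndarray:
        return _sigmoid(np.clip(self.linear_predictor(X), -LOGIT_CLIP, LOGIT_CLIP))


def _design(X) -> np.ndarray:
    if X is None:
        return np.zeros((0, 0))
    if isinstance(X, CovariateDesign):
        return X.X
    return np.asarray(X, dtype=float)


def penalized_loglik(
    B: DetectionMatrix | np.ndarray,
    fit: ScbfaFit,
    X=None,
    hyper: ScbfaHyper | None = None,
) -> float:
    """Penalized Bernoulli log-likelihood at the given parameters.

    Logits are clipped to +/-30 before the sigmoid so the Bernoulli terms
    never evaluate log(0).
    """
    Bv = B.values if isinstance(B, DetectionMatrix) else np.asarray(B)
    Xv = _design(X)
    hyper = hyper or fit.hyper
    if hyper is None:
        raise ValueError("hyperparameters required")
    hyper = hyper.resolve(*Bv.shape)
    for arr in (fit.Z, fit.A, fit.beta, fit.u, fit.v):
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("NaN/inf in model parameters")
    eta = np.clip(
        fit.linear_predictor(Xv if Xv.size else None), -LOGIT_CLIP, LOGIT_CLIP
    )
    mu = _sigmoid(eta)
    ll = float(np.sum(Bv * np.log(mu) + (1 - Bv) * np.log1p(-mu)))
    ll -= hyper.eps1 * float(np.sum(fit.A**2))
    ll -= hyper.eps2 * float(np.sum(fit.Z**2))
    if fit.beta.size:
        ll -= hyper.eps3 * float(np.sum(fit.beta**2))
    return ll


def gradient(
    B: DetectionMatrix | np.ndarray,
    fit: ScbfaFit,
    X=None,
    hyper: ScbfaHyper | None = None,
) -> dict:
    """Analytic gradient of :func:`penalized_loglik` w.r.t. each parameter block."""
    Bv = B.values if isinstance(B, DetectionMatrix) else np.asarray(B)
    Xv = _design(X)
    hyper = (hyper or fit.hyper).resolve(*Bv.shape)
    eta = np.clip(
        fit.linear_predictor(Xv if Xv.size else None), -LOGIT_CLIP, LOGIT_CLIP
    )
    R = Bv - _sigmoid(eta)  # N x G residual
    grad = {
        "Z": R @ fit.A.T - 2 * hyper.eps2 * fit.Z,
        "A": fit.Z.T @ R - 2 * hyper.eps1 * fit.A,
        "u": R.sum(axis=1),
        "v": R.sum(axis=0),
    }
    grad["beta"] = (
        Xv.T @ R - 2 * hyper.eps3 * fit.beta
        if fit.beta.size
        else np.zeros_like(fit.beta)
    )
    return grad


def _svd_sign_fix(Z: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic orientation: largest-|loading| entry per factor positive
    for k in range(A.shape[0]):
        j = np.argmax(np.abs(A[k]))
        if A[k, j] < 0:
            A[k] = -A[k]
            Z[:, k] = -Z[:, k]
    return Z, A


def orthogonalize(Z: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rebalance a factorization by an SVD split of the product.

    With Z A = U D V', returns Z' = U D^{1/2} and A' = D^{1/2} V' restricted to
    the leading K singular values, so the product is preserved, columns of Z'
    are orthogonal, and ||Z'||_F = ||A'||_F. Factors are ordered by decreasing
    singular value with the largest-magnitude loading per factor positive.
    """
    Z = np.asarray(Z, dtype=float)
    A = np.asarray(A, dtype=float)
    K = Z.shape[1]
    if A.shape[0] != K:
        raise ValueError("Z and A have incompatible inner dimensions")
    U, d, Vt = np.linalg.svd(Z @ A, full_matrices=False)
    U, d, Vt = U[:, :K], d[:K], Vt[:K]
    root = np.sqrt(d)
    return _svd_sign_fix(U * root, root[:, None] * Vt)


def _init_params(Bv: np.ndarray, K: int, C: int, seed: int):
    n, g = Bv.shape
    cell_rate = np.clip(Bv.mean(axis=1), _INIT_RATE_CLIP, 1 - _INIT_RATE_CLIP)
    gene_rate = np.clip(Bv.mean(axis=0), _INIT_RATE_CLIP, 1 - _INIT_RATE_CLIP)
    grand = np.clip(Bv.mean(), _INIT_RATE_CLIP, 1 - _INIT_RATE_CLIP)
    u0 = _logit(cell_rate)
    v0 = _logit(gene_rate) - _logit(grand)
    rng = np.random.default_rng(seed)
    Z0 = rng.normal(0.0, 0.1, size=(n, K))
    A0 = rng.normal(0.0, 0.1, size=(K, g))
    beta0 = rng.normal(0.0, 0.1, size=(C, g)) if C else np.zeros((0, g))
    return Z0, A0, beta0, u0, v0


def fit_scbfa(
    B: DetectionMatrix,
    X: CovariateDesign | None = None,
    hyper: ScbfaHyper | None = None,
    fixed_beta: np.ndarray | None = None,
) -> ScbfaFit:
    """Fit the detection factor model by joint quasi-Newton optimization.

    All parameter blocks are concatenated into a single vector handed to one
    L-BFGS-B call. Initialization: u from per-cell detection-rate logits, v
    from per-gene detection-rate logits minus the grand-mean logit, Z/A/beta
    from N(0, 0.1^2) under ``hyper.seed``. When ``fixed_beta`` is given the
    covariate coefficients are frozen (batch plug-in scheme) and only the
    remaining blocks are optimized.

    Non-convergence within ``max_iter`` iterations is reported through
    ``converged=False`` on the returned fit, not an exception.
    """
    Bv = np.asarray(B.values, dtype=float)
    n, g = Bv.shape
    total = Bv.sum()
    if total == 0 or total == Bv.size:
        raise ValueError("degenerate detection matrix: needs at least one 0 and one 1")
    col_rates = Bv.mean(axis=0)
    degenerate = np.where((col_rates == 0) | (col_rates == 1))[0]
    if degenerate.size:
        ids = [str(B.feature_ids[j]) for j in degenerate[:5]]
        raise ValueError(
            f"{degenerate.size} features are detected in no cell or in every "
            f"cell (e.g. {ids}); their intercepts diverge — run qc_filter first"
        )
    hyper = (hyper or ScbfaHyper()).resolve(n, g)
    if hyper.K >= min(n, g):  # K < G (and K < N) so the factorization is low-rank
        raise ValueError(f"K={hyper.K} must be < min(N, G) = {min(n, g)}")
    Xv = _design(X)
    C = Xv.shape[1] if Xv.size else 0

    Z0, A0, beta0, u0, v0 = _init_params(Bv, hyper.K, C, hyper.seed)
    if fixed_beta is not None:
        fixed_beta = np.asarray(fixed_beta, dtype=float)
        if fixed_beta.shape != (C, g):
            raise ValueError(f"fixed_beta must have shape ({C}, {g})")

    shapes = {"Z": (n, hyper.K), "A": (hyper.K, g), "u": (n,), "v": (g,)}
    free_beta = C > 0 and fixed_beta is None
    if free_beta:
        shapes["beta"] = (C, g)

    keys = list(shapes)
    sizes = {k: int(np.prod(shapes[k])) for k in keys}

    def pack(params: dict) -> np.ndarray:
        return np.concatenate([params[k].ravel() for k in keys])

    def unpack(theta: np.ndarray) -> dict:
        out, ofs = {}, 0
        for k in keys:
            out[k] = theta[ofs : ofs + sizes[k]].reshape(shapes[k])
            ofs += sizes[k]
        return out

    beta_const = fixed_beta if fixed_beta is not None else np.zeros((0, g))

    def make_fit(p: dict) -> ScbfaFit:
        return ScbfaFit(
            Z=p["Z"], A=p["A"],
            beta=p["beta"] if free_beta else beta_const,
            u=p["u"], v=p["v"], hyper=hyper,
        )

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        p = unpack(theta)
        f = make_fit(p)
        nll = -penalized_loglik(Bv, f, Xv if C else None, hyper)
        gr = gradient(Bv, f, Xv if C else None, hyper)
        gvec = np.concatenate([-gr[k].ravel() for k in keys])
        return nll, gvec

    trace: list[float] = []

    def callback(theta: np.ndarray) -> None:
        p = unpack(theta)
        trace.append(penalized_loglik(Bv, make_fit(p), Xv if C else None, hyper))

    theta0 = pack(
        {"Z": Z0, "A": A0, "u": u0, "v": v0, **({"beta": beta0} if free_beta else {})}
    )
    trace.append(
        penalized_loglik(Bv, make_fit(unpack(theta0)), Xv if C else None, hyper)
    )
    res = scipy.optimize.minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={"maxiter": hyper.max_iter, "ftol": hyper.tol},
    )
    p = unpack(res.x)
    fit = make_fit(p)
    fit.Z, fit.A = orthogonalize(fit.Z, fit.A)
    fit.objective_trace = trace
    fit.converged = bool(res.success)
    return fit


def binary_pca(counts_or_B, K: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of the (column-centered, unscaled) detection matrix.

    Counts are binarized first, so the output is identical for a count matrix
    and its detection pattern. Columns are centered but deliberately not
    scaled to unit variance: detection variance carries cell-type signal and
    should contribute to the embedding. Returns ``(embeddings N x K,
    loadings K x G, explained_variance K)``.
    """
    from .preprocess import binarize  # local import avoids a cycle

    B = binarize(counts_or_B)
    Bv = B.values.astype(float)
    n, g = Bv.shape
    if K > min(n - 1, g):
        raise ValueError(f"K={K} too large for a {n} x {g} matrix")
    centered = Bv - Bv.mean(axis=0)
    U, d, Vt = np.linalg.svd(centered, full_matrices=False)
    U, d, Vt = U[:, :K], d[:K], Vt[:K]
    scores = U * d
    loadings = Vt
    scores, loadings = _svd_sign_fix(scores, loadings)
    explained = d**2 / (n - 1)
    return scores, loadings, explained
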