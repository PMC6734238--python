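import numpy as np
import pytest
import scipy.optimize
from scipy.special import expit, logit
from sklearn.metrics import roc_auc_score

from scbfa import model
from scbfa.model import (
    CovariateDesign,
    ScbfaFit,
    ScbfaHyper,
    binary_pca,
    fit_scbfa,
    gradient,
    orthogonalize,
    penalized_loglik,
    standardize_covariates,
)

from .conftest import make_counts, make_detection


def random_fit(rng, n, g, k, c=0):
    return ScbfaFit(
        Z=rng.normal(0, 0.5, (n, k)),
        A=rng.normal(0, 0.5, (k, g)),
        beta=rng.normal(0, 0.5, (c, g)) if c else np.zeros((0, g)),
        u=rng.normal(0, 0.5, n),
        v=rng.normal(0, 0.5, g),
    )


def model_generated_detection(
    rng, n=200, g=100, k=2, centroid_scale=4.0, loading_scale=5.0
):
    """Sample B from the Bernoulli factor model with strong cluster structure.

    Returns (DetectionMatrix, true mu) restricted to nondegenerate columns.
    """
    centroids = rng.normal(0, centroid_scale, (2, k))
    Z = centroids[np.repeat([0, 1], n // 2)] + rng.normal(0, 0.3, (n, k))
    A = rng.normal(0, loading_scale / np.sqrt(k), (k, g))
    u = rng.normal(0, 0.3, n)
    v = rng.normal(0, 2.0, g)
    mu = expit(Z @ A + u[:, None] + v[None, :])
    B = (rng.uniform(size=(n, g)) < mu).astype(np.int8)
    col = B.mean(axis=0)
    keep = (col > 0) & (col < 1)
    return make_detection(B[:, keep]), mu[:, keep]


class TestStandardizeCovariates:
    def test_column_123(self):
        design = standardize_covariates(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(
            design.X.ravel(), [-1.22474487, 0.0, 1.22474487], atol=1e-8
        )

    def test_idempotent(self, rng):
        X = rng.normal(size=(50, 2))
        X = (X - X.mean(0)) / X.std(0)
        design = standardize_covariates(X)
        np.testing.assert_allclose(design.X, X, atol=1e-12)

    def test_constant_column_named(self):
        X = np.column_stack([np.ones(5), np.arange(5)])
        with pytest.raises(ValueError, match="cov0"):
            standardize_covariates(X)

    def test_transform_reuses_scaling(self, rng):
        X = rng.normal(2.0, 3.0, size=(40, 2))
        design = standardize_covariates(X)
        np.testing.assert_allclose(design.transform(X[:10]), design.X[:10])


class TestPenalizedLoglik:
    def test_all_zero_parameters(self):
        n, g = 4, 6
        B = make_detection(np.eye(4, 6, dtype=int))
        fit = ScbfaFit(Z=np.zeros((n, 2)), A=np.zeros((2, g)),
                       beta=np.zeros((0, g)), u=np.zeros(n), v=np.zeros(g))
        val = penalized_loglik(B, fit, hyper=ScbfaHyper(K=2))
        np.testing.assert_allclose(val, n * g * np.log(0.5))

    def test_single_cell_gene(self):
        B = make_detection([[1]])
        fit = ScbfaFit(Z=np.zeros((1, 1)), A=np.zeros((1, 1)),
                       beta=np.zeros((0, 1)), u=np.array([logit(0.9)]),
                       v=np.zeros(1))
        hyper = ScbfaHyper(K=1, eps0=0.0, eps1=0.0, eps2=0.0, eps3=0.0)
        val = penalized_loglik(B.values, fit, hyper=hyper)
        np.testing.assert_allclose(val, np.log(0.9))

    def test_penalty_additivity(self, rng):
        B = make_detection(rng.integers(0, 2, (6, 5)))
        fit = random_fit(rng, 6, 5, 2)
        base = ScbfaHyper(K=2, eps1=0.0, eps2=0.0, eps3=0.0)
        with_pen = ScbfaHyper(K=2, eps1=0.0, eps2=0.7, eps3=0.0)
        v0 = penalized_loglik(B, fit, hyper=base)
        v1 = penalized_loglik(B, fit, hyper=with_pen)
        np.testing.assert_allclose(v0 - v1, 0.7 * np.sum(fit.Z**2))

    def test_nan_rejected(self, rng):
        B = make_detection(rng.integers(0, 2, (4, 5)))
        fit = random_fit(rng, 4, 5, 2)
        fit.u[0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            penalized_loglik(B, fit, hyper=ScbfaHyper(K=2))


def numerical_gradient(B, fit, X, hyper, eps=1e-6):
    """Central finite differences of penalized_loglik over every parameter."""
    out = {}
    for name in ("Z", "A", "beta", "u", "v"):
        arr = getattr(fit, name)
        g = np.zeros_like(arr, dtype=float)
        if arr.size == 0:
            out[name] = g
            continue
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            up = penalized_loglik(B, fit, X, hyper)
            arr[idx] = orig - eps
            down = penalized_loglik(B, fit, X, hyper)
            arr[idx] = orig
            g[idx] = (up - down) / (2 * eps)
        out[name] = g
    return out


class TestGradient:
    def test_matches_finite_differences(self, rng):
        for trial in range(20):
            n = int(rng.integers(3, 12))
            g = int(rng.integers(3, 12))
            k = int(rng.integers(1, 4))
            c = int(rng.integers(0, 3))
            B = rng.integers(0, 2, (n, g)).astype(float)
            fit = random_fit(rng, n, g, k, c)
            X = rng.normal(size=(n, c)) if c else None
            hyper = ScbfaHyper(
                K=k, eps1=float(rng.uniform(0, 2)), eps2=float(rng.uniform(0, 2)),
                eps3=float(rng.uniform(0, 2)),
            )
            analytic = gradient(B, fit, X, hyper)
            numeric = numerical_gradient(B, fit, X, hyper)
            for name, num in numeric.items():
                if num.size == 0:
                    continue
                ref = max(np.abs(num).max(), 1.0)
                assert np.abs(analytic[name] - num).max() / ref < 1e-5, (
                    trial, name
                )

    def test_zero_at_numerical_optimum(self, rng):
        n, g, k = 5, 4, 2
        B = rng.integers(0, 2, (n, g)).astype(float)
        hyper = ScbfaHyper(K=k, eps1=0.5, eps2=0.5, eps3=0.5)

        sizes = [(n, k), (k, g), (n,), (g,)]

        def unpack(theta):
            out, ofs = [], 0
            for shape in sizes:
                m = int(np.prod(shape))
                out.append(theta[ofs:ofs + m].reshape(shape))
                ofs += m
            return out

        def nll(theta):
            Z, A, u, v = unpack(theta)
            fit = ScbfaFit(Z=Z, A=A, beta=np.zeros((0, g)), u=u, v=v)
            return -penalized_loglik(B, fit, hyper=hyper)

        # independent route: derivative-free/numeric-jac quasi-Newton
        theta0 = rng.normal(0, 0.1, sum(int(np.prod(s)) for s in sizes))
        res = scipy.optimize.minimize(
            nll, theta0, method="L-BFGS-B", jac="3-point",
            options={"maxiter": 5000, "ftol": 1e-16, "gtol": 1e-10},
        )
        Z, A, u, v = unpack(res.x)
        fit = ScbfaFit(Z=Z, A=A, beta=np.zeros((0, g)), u=u, v=v)
        grad = gradient(B, fit, hyper=hyper)
        norm = max(np.abs(grad[k0]).max() for k0 in ("Z", "A", "u", "v"))
        assert norm < 1e-5

    def test_symmetric_intercept_gradients_zero(self):
        B = np.array([[0, 1, 0, 1], [1, 0, 1, 0], [1, 1, 0, 0], [0, 0, 1, 1]],
                     dtype=float)
        n, g = B.shape
        fit = ScbfaFit(Z=np.zeros((n, 2)), A=np.zeros((2, g)),
                       beta=np.zeros((0, g)), u=np.zeros(n), v=np.zeros(g))
        grad = gradient(B, fit, hyper=ScbfaHyper(K=2))
        np.testing.assert_allclose(grad["u"], 0, atol=1e-12)
        np.testing.assert_allclose(grad["v"], 0, atol=1e-12)


class TestFit:
    def test_generative_self_consistency(self, rng):
        B, _ = model_generated_detection(rng)
        fit = fit_scbfa(B, hyper=ScbfaHyper(K=2, seed=1))
        auroc = roc_auc_score(B.values.ravel(), fit.predicted_mu().ravel())
        assert auroc > 0.95

    def test_seed_stability(self, rng):
        B, _ = model_generated_detection(rng)
        f1 = fit_scbfa(B, hyper=ScbfaHyper(K=2, seed=1))
        f2 = fit_scbfa(B, hyper=ScbfaHyper(K=2, seed=2))
        o1, o2 = f1.objective_trace[-1], f2.objective_trace[-1]
        assert abs(o1 - o2) / abs(o1) < 1e-3

    def test_one_factor_separates_blocks(self, rng):
        # two cell blocks with complementary detection patterns (high on one
        # gene half, low on the other); a uniform rate difference would be
        # absorbed by the cell intercepts, a pattern difference cannot be
        p = np.where(np.arange(30) < 15, 0.9, 0.1)
        top = (rng.uniform(size=(20, 30)) < p).astype(int)
        bottom = (rng.uniform(size=(20, 30)) < p[::-1]).astype(int)
        B = np.vstack([top, bottom])
        col = B.mean(axis=0)
        B = B[:, (col > 0) & (col < 1)]
        fit = fit_scbfa(make_detection(B), hyper=ScbfaHyper(K=1, seed=0))
        z = fit.Z[:, 0]
        side_a, side_b = z[:20], z[20:]
        assert side_a.min() > side_b.max() or side_b.min() > side_a.max()

    def test_objective_trace_monotone(self, rng):
        B, _ = model_generated_detection(rng, n=80, g=40)
        fit = fit_scbfa(B, hyper=ScbfaHyper(K=2, seed=0))
        tr = np.array(fit.objective_trace)
        assert np.all(np.diff(tr) >= -1e-6 * np.maximum(np.abs(tr[:-1]), 1.0))

    def test_scale_invariance_of_counts(self, rng):
        from scbfa.preprocess import binarize

        values = rng.poisson(1.0, size=(40, 25))
        values[:, values.sum(0) == 0] += 1  # avoid degenerate all-zero columns
        cm1 = make_counts(values)
        cm7 = make_counts(values * 7)
        f1 = fit_scbfa(binarize(cm1), hyper=ScbfaHyper(K=2, seed=3))
        f7 = fit_scbfa(binarize(cm7), hyper=ScbfaHyper(K=2, seed=3))
        np.testing.assert_array_equal(f1.Z, f7.Z)
        np.testing.assert_array_equal(f1.A, f7.A)

    def test_embedding_shrinks_with_eps2(self, rng):
        B, _ = model_generated_detection(rng, n=60, g=40)
        norms = []
        for eps2 in (1.0, 50.0, 2000.0):
            fit = fit_scbfa(B, hyper=ScbfaHyper(K=2, eps2=eps2, seed=0))
            norms.append(np.linalg.norm(fit.Z))
        assert norms[0] > norms[1] > norms[2]

    def test_degenerate_feature_rejected(self, rng):
        B = rng.integers(0, 2, (10, 5))
        B[:, 2] = 1
        with pytest.raises(ValueError, match="qc_filter"):
            fit_scbfa(make_detection(B), hyper=ScbfaHyper(K=1))

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_scbfa(make_detection(np.ones((5, 4), dtype=int)),
                      hyper=ScbfaHyper(K=1))

    def test_nonconvergence_flagged_not_raised(self, rng):
        B, _ = model_generated_detection(rng, n=60, g=40)
        fit = fit_scbfa(B, hyper=ScbfaHyper(K=2, seed=0, max_iter=2))
        assert fit.converged is False

    def test_covariate_absorption(self, rng):
        # batch enters as a gene-wise logit offset; including X should reduce
        # the association between every factor and the batch label
        n, g, k = 150, 60, 2
        batch = np.repeat([0.0, 1.0], n // 2)
        x = (batch - batch.mean()) / batch.std()
        centroids = rng.normal(0, 2.0, (2, k))
        Z = centroids[np.tile([0, 1], n // 2)] + rng.normal(0, 0.3, (n, k))
        A = rng.normal(0, 1.5 / np.sqrt(k), (k, g))
        beta = rng.normal(0, 2.0, g)
        eta = Z @ A + x[:, None] * beta[None, :] + rng.normal(0, 0.3, n)[:, None]
        B = (rng.uniform(size=(n, g)) < expit(eta)).astype(int)
        col = B.mean(0)
        B = B[:, (col > 0) & (col < 1)]
        Bm = make_detection(B)
        design = standardize_covariates(batch[:, None], ["batch"])
        fit_plain = fit_scbfa(Bm, hyper=ScbfaHyper(K=k, seed=0))
        fit_cov = fit_scbfa(Bm, X=design, hyper=ScbfaHyper(K=k, seed=0))

        def batch_assoc(fit):
            return max(
                abs(np.corrcoef(fit.Z[:, j], batch)[0, 1]) for j in range(k)
            )

        assert batch_assoc(fit_cov) < batch_assoc(fit_plain)


class TestOrthogonalize:
    def test_hand_svd_2x2(self):
        Zp, Ap = orthogonalize(2 * np.eye(2), np.eye(2))
        np.testing.assert_allclose(Zp, np.sqrt(2) * np.eye(2), atol=1e-12)
        np.testing.assert_allclose(Ap, np.sqrt(2) * np.eye(2), atol=1e-12)

    def test_balanced_pair_fixed_point(self, rng):
        # construct an already balanced orthogonal pair from an SVD
        M = rng.normal(size=(6, 5))
        U, d, Vt = np.linalg.svd(M, full_matrices=False)
        K = 3
        Z = U[:, :K] * np.sqrt(d[:K])
        A = np.sqrt(d[:K])[:, None] * Vt[:K]
        Zp, Ap = orthogonalize(Z, A)
        np.testing.assert_allclose(np.abs(Zp), np.abs(Z), atol=1e-10)
        np.testing.assert_allclose(np.abs(Ap), np.abs(A), atol=1e-10)

    def test_product_preserved_and_balanced(self, rng):
        Z = rng.normal(size=(10, 3))
        A = rng.normal(size=(3, 8))
        Zp, Ap = orthogonalize(Z, A)
        prod = Z @ A
        assert np.linalg.norm(Zp @ Ap - prod) <= 1e-10 * np.linalg.norm(prod)
        assert abs(np.linalg.norm(Zp) - np.linalg.norm(Ap)) < 1e-10
        gram = Zp.T @ Zp
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_preserves_linear_predictor(self, rng):
        B, _ = model_generated_detection(rng, n=60, g=40)
        fit = fit_scbfa(B, hyper=ScbfaHyper(K=2, seed=0))
        Zp, Ap = orthogonalize(fit.Z, fit.A)
        np.testing.assert_allclose(Zp @ Ap, fit.Z @ fit.A, atol=1e-8)


class TestBinaryPca:
    def test_constant_column_zero_loading(self, rng):
        values = rng.integers(0, 3, (12, 6))
        values[:, 4] = 1
        scores, loadings, _ = binary_pca(make_counts(values), 2)
        np.testing.assert_allclose(loadings[:, 4], 0, atol=1e-10)

    def test_counts_equal_binarized(self, rng):
        from scbfa.preprocess import binarize

        values = rng.poisson(2.0, (15, 8))
        cm = make_counts(values)
        s1, l1, e1 = binary_pca(cm, 3)
        s2, l2, e2 = binary_pca(binarize(cm), 3)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(l1, l2)

    def test_matches_eigendecomposition_oracle(self, rng):
        values = (rng.uniform(size=(10, 8)) < 0.4).astype(int)
        scores, loadings, explained = binary_pca(make_counts(values), 3)
        centered = values - values.mean(axis=0)
        cov = centered.T @ centered / (10 - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][:3]
        np.testing.assert_allclose(explained, evals[order], atol=1e-10)
        for k in range(3):
            v = evecs[:, order[k]]
            dot = abs(v @ loadings[k])
            np.testing.assert_allclose(dot, 1.0, atol=1e-8)
            np.testing.assert_allclose(
                np.abs(centered @ v), np.abs(scores[:, k]), atol=1e-8
            )

    def test_k_too_large(self, rng):
        cm = make_counts(rng.integers(0, 2, (5, 4)))
        with pytest.raises(ValueError):
            binary_pca(cm, 5)

    def test_hand_4x3(self):
        values = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]])
        scores, loadings, explained = binary_pca(make_counts(values), 2)
        centered = values - values.mean(axis=0)
        np.testing.assert_allclose(
            scores @ loadings + values.mean(axis=0) - values, 0, atol=1.0
        )  # rank-2 approximation of a rank-3 matrix: bounded error
        assert explained[0] >= explained[1] >= 0
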