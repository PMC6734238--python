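"""Generative simulator with independent detection-noise and count-noise
channels.

A shared ground-truth embedding Z_hat drives both channels. Per dataset, the
count-channel embedding Z_mu and the detection-channel embedding Z_pi are
drawn from Gaussians centered on Z_hat with spherical variances sigma2_mu and
sigma2_pi. Dropout probabilities follow
``logit(pi_ij) = z_pi(i)' a_pi(j) + u_pi(i) + v_pi(j) - delta`` (larger delta
means fewer dropouts), count means follow
``log(mu_ij) = z_mu(i)' a_mu(j) + u_mu(i) + v_mu(j)``, the dropout indicator
is Bernoulli(pi), and non-dropout counts are negative binomial with mean mu
and size r (variance mu + mu^2 / r, r shared across genes).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .data import CountMatrix

#: parameter grids yielding 5 x 5 x 5 x 3 = 375 unique settings
DELTA_GRID = (-2.0, -0.5, 1.0, 2.5, 4.0)
SIGMA2_GRID = (0.1, 0.5, 1.0, 2.0, 3.0)
R_GRID = (0.5, 1.0, 5.0)

_LOGMU_MAX = 30.0


@dataclass
class SimulationTruth:
    """Ground-truth embedding and generative parameters, plus cell-type labels."""

    Z_hat: np.ndarray   # N x K shared embedding
    A_mu: np.ndarray    # K x G count-channel loadings
    A_pi: np.ndarray    # K x G dropout-channel loadings
    u_mu: np.ndarray    # N cell intercepts, count channel
    u_pi: np.ndarray    # N cell intercepts, dropout channel
    v_mu: np.ndarray    # G gene intercepts, count channel
    v_pi: np.ndarray    # G gene intercepts, dropout channel
    labels: np.ndarray  # N cell-type ids

    @property
    def n_cells(self) -> int:
        return self.Z_hat.shape[0]

    @property
    def n_features(self) -> int:
        return self.A_mu.shape[1]

    @property
    def K(self) -> int:
        return self.Z_hat.shape[1]

    def subset_cells(self, idx: np.ndarray) -> "SimulationTruth":
        return SimulationTruth(
            Z_hat=self.Z_hat[idx], A_mu=self.A_mu, A_pi=self.A_pi,
            u_mu=self.u_mu[idx], u_pi=self.u_pi[idx],
            v_mu=self.v_mu, v_pi=self.v_pi, labels=self.labels[idx],
        )

    def subset_features(self, idx: np.ndarray) -> "SimulationTruth":
        return SimulationTruth(
            Z_hat=self.Z_hat, A_mu=self.A_mu[:, idx], A_pi=self.A_pi[:, idx],
            u_mu=self.u_mu, u_pi=self.u_pi,
            v_mu=self.v_mu[idx], v_pi=self.v_pi[idx], labels=self.labels,
        )


@dataclass
class NoiseSetting:
    """One point of the noise grid (plus replicate index and seed)."""

    delta: float
    sigma2_pi: float
    sigma2_mu: float
    r: float
    replicate: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2_pi < 0 or self.sigma2_mu < 0:
            raise ValueError("sigma2 values must be nonnegative")
        if self.r <= 0:
            raise ValueError("NB size r must be positive")

    def to_dict(self) -> dict:
        return {
            "delta": self.delta, "sigma2_pi": self.sigma2_pi,
            "sigma2_mu": self.sigma2_mu, "r": self.r,
            "replicate": self.replicate, "seed": self.seed,
        }


@dataclass
class SimulatedDataset:
    """A simulated count matrix plus every latent quantity that produced it."""

    counts: CountMatrix
    dropout_indicators: np.ndarray  # N x G in {0,1}
    pi: np.ndarray                  # N x G dropout probabilities
    mu: np.ndarray                  # N x G NB means
    Z_pi: np.ndarray
    Z_mu: np.ndarray
    truth: SimulationTruth
    setting: NoiseSetting

    @property
    def labels(self) -> np.ndarray:
        return self.truth.labels


def _nb_zero_prob(mu: np.ndarray, r: float) -> np.ndarray:
    return (r / (r + mu)) ** r


def make_ground_truth(
    n_cells: int,
    n_features: int,
    K: int = 5,
    n_celltypes: int = 4,
    baseline_detection: float = 0.5,
    seed: int = 0,
    centroid_scale: float = 1.0,
    jitter_sd: float = 0.2,
    calibration_r: float = 1.0,
    count_intercept_loc: float = float(np.log(8.0)),
) -> SimulationTruth:
    """Draw cluster-structured ground-truth parameters.

    Cells are assigned to ``n_celltypes`` near-equal blocks; each type gets a
    Gaussian centroid in K-space and cells get within-type jitter. Loadings
    are Gaussian with scale 1/sqrt(K) so logit/log ranges stay realistic. The
    dropout-channel gene intercepts are shifted by a 1-d root find so the
    expected detection rate at delta = 0 (accounting for negative-binomial
    zeros at dispersion ``calibration_r``) matches ``baseline_detection``.
    """
    if not (0 < baseline_detection < 1):
        raise ValueError("baseline_detection must lie strictly in (0, 1)")
    if n_celltypes > n_cells:
        raise ValueError("more cell types than cells")
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)

    centroids = rng.normal(0.0, centroid_scale, size=(n_celltypes, K))
    labels = np.array(
        [f"type{t}" for t in np.repeat(np.arange(n_celltypes),
                                       -(-n_cells // n_celltypes))[:n_cells]],
        dtype=object,
    )
    type_index = np.array([int(s[4:]) for s in labels])
    Z_hat = centroids[type_index] + rng.normal(0.0, jitter_sd, size=(n_cells, K))

    scale = 1.0 / np.sqrt(K)
    A_mu = rng.normal(0.0, scale, size=(K, n_features))
    A_pi = rng.normal(0.0, scale, size=(K, n_features))
    u_mu = rng.normal(0.0, 0.3, size=n_cells)
    u_pi = rng.normal(0.0, 0.3, size=n_cells)
    v_mu = rng.normal(count_intercept_loc, 0.7, size=n_features)
    v_pi = rng.normal(0.0, 0.5, size=n_features)

    # calibrate the global dropout intercept: detection needs both no dropout
    # and a nonzero NB draw
    eta_pi = Z_hat @ A_pi + u_pi[:, None] + v_pi[None, :]
    log_mu = Z_hat @ A_mu + u_mu[:, None] + v_mu[None, :]
    mu = np.exp(np.clip(log_mu, -_LOGMU_MAX, _LOGMU_MAX))
    p_nonzero = 1.0 - _nb_zero_prob(mu, calibration_r)

    def expected_gdr(c: float) -> float:
        return float(np.mean((1.0 - expit(eta_pi - c)) * p_nonzero))

    lo, hi = -50.0, 50.0
    if expected_gdr(hi) < baseline_detection:
        raise ValueError(
            "baseline_detection unattainable: too many structural NB zeros"
        )
    c = brentq(lambda x: expected_gdr(x) - baseline_detection, lo, hi, xtol=1e-10)
    v_pi = v_pi - c

    return SimulationTruth(
        Z_hat=Z_hat, A_mu=A_mu, A_pi=A_pi,
        u_mu=u_mu, u_pi=u_pi, v_mu=v_mu, v_pi=v_pi, labels=labels,
    )


def simulate_dataset(truth: SimulationTruth, setting: NoiseSetting) -> SimulatedDataset:
    """Sample one dataset from the two-channel generative model.

    All randomness comes from ``setting.seed``. The negative-binomial draws
    are generated for every entry before masking with the dropout indicator,
    so datasets simulated with paired seeds but different ``delta`` share
    their count draws and differ monotonically in the dropout mask.
    """
    rng = np.random.default_rng(setting.seed)
    n, g, k = truth.n_cells, truth.n_features, truth.K

    Z_mu = truth.Z_hat + rng.normal(0.0, np.sqrt(setting.sigma2_mu), size=(n, k))
    Z_pi = truth.Z_hat + rng.normal(0.0, np.sqrt(setting.sigma2_pi), size=(n, k))

    eta_pi = Z_pi @ truth.A_pi + truth.u_pi[:, None] + truth.v_pi[None, :] - setting.delta
    pi = expit(eta_pi)
    log_mu = Z_mu @ truth.A_mu + truth.u_mu[:, None] + truth.v_mu[None, :]
    if np.any(log_mu > _LOGMU_MAX):
        raise OverflowError(
            "log(mu) exceeds the overflow guard; rescale the ground-truth "
            "loadings/intercepts"
        )
    mu = np.exp(log_mu)

    dropout = (rng.uniform(size=(n, g)) < pi).astype(np.int8)
    p = setting.r / (setting.r + mu)
    nb = rng.negative_binomial(setting.r, p)
    values = np.where(dropout == 1, 0, nb).astype(np.int64)

    counts = CountMatrix(
        values=values,
        cell_ids=np.array([f"cell{i}" for i in range(n)], dtype=object),
        feature_ids=np.array([f"gene{j}" for j in range(g)], dtype=object),
    )
    return SimulatedDataset(
        counts=counts, dropout_indicators=dropout, pi=pi, mu=mu,
        Z_pi=Z_pi, Z_mu=Z_mu, truth=truth, setting=setting,
    )


def qc_filter_simulated(data: SimulatedDataset) -> SimulatedDataset:
    """Two-pass filter: drop genes detected in < 1% of cells, then cells
    detecting < 1% of the remaining genes. Truth and latent matrices are
    subset alongside the counts."""
    detected = data.counts.values >= 1
    keep_genes = detected.mean(axis=0) >= 0.01
    if not keep_genes.any():
        raise ValueError("all genes removed by the simulated-data QC filter")
    gidx = np.where(keep_genes)[0]
    detected = detected[:, gidx]
    keep_cells = detected.mean(axis=1) >= 0.01
    if not keep_cells.any():
        raise ValueError("all cells removed by the simulated-data QC filter")
    cidx = np.where(keep_cells)[0]

    truth = data.truth.subset_features(gidx).subset_cells(cidx)
    sub = np.ix_(cidx, gidx)
    return SimulatedDataset(
        counts=data.counts.subset(cells=cidx, features=gidx),
        dropout_indicators=data.dropout_indicators[sub],
        pi=data.pi[sub],
        mu=data.mu[sub],
        Z_pi=data.Z_pi[cidx],
        Z_mu=data.Z_mu[cidx],
        truth=truth,
        setting=data.setting,
    )


def _setting_seed(base_seed: int, coords: tuple[int, ...]) -> int:
    # SeedSequence spawn keys give reproducible, well-separated streams
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=coords)
    return int(ss.generate_state(1)[0])


def simulation_grid(
    deltas=DELTA_GRID,
    sigma2_pis=SIGMA2_GRID,
    sigma2_mus=SIGMA2_GRID,
    rs=R_GRID,
    replicates: int = 3,
    base_seed: int = 0,
) -> list[NoiseSetting]:
    """Cartesian product of the noise grids x replicates.

    The default grids enumerate 5 x 5 x 5 x 3 = 375 unique parameter settings;
    with 3 replicates each that is 1125 datasets. Per-setting seeds are
    derived deterministically from ``base_seed`` and the grid coordinates.
    """
    settings = []
    for (di, delta), (pi_, s2pi), (mi, s2mu), (ri, r) in itertools.product(
        enumerate(deltas), enumerate(sigma2_pis), enumerate(sigma2_mus), enumerate(rs)
    ):
        for rep in range(replicates):
            settings.append(
                NoiseSetting(
                    delta=delta, sigma2_pi=s2pi, sigma2_mu=s2mu, r=r,
                    replicate=rep,
                    seed=_setting_seed(base_seed, (di, pi_, mi, ri, rep)),
                )
            )
    return settings


def poisson_resample(
    rates: np.ndarray, size_factors: np.ndarray, seed: int = 0
) -> CountMatrix:
    """Resample counts O_ij ~ Poisson(s_i * rate_ij) from imputed rates.

    ``size_factors`` are per-cell library sizes divided by the mean library
    size across cells.
    """
    rates = np.asarray(rates, dtype=float)
    size_factors = np.asarray(size_factors, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("rates must be strictly positive")
    if np.any(size_factors <= 0):
        raise ValueError("size factors must be strictly positive")
    if rates.ndim != 2 or size_factors.shape != (rates.shape[0],):
        raise ValueError("rates must be N x G with one size factor per cell")
    rng = np.random.default_rng(seed)
    values = rng.poisson(size_factors[:, None] * rates)
    n, g = rates.shape
    return CountMatrix(
        values=values,
        cell_ids=np.array([f"cell{i}" for i in range(n)], dtype=object),
        feature_ids=np.array([f"gene{j}" for j in range(g)], dtype=object),
    )
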