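import numpy as np
import pytest

from scbfa.data import CountMatrix, DetectionMatrix


def make_counts(values, mito=None) -> CountMatrix:
    values = np.asarray(values)
    n, g = values.shape
    return CountMatrix(
        values=values,
        cell_ids=np.array([f"cell{i}" for i in range(n)], dtype=object),
        feature_ids=np.array([f"gene{j}" for j in range(g)], dtype=object),
        feature_is_mito=mito,
    )


def make_detection(values) -> DetectionMatrix:
    values = np.asarray(values)
    n, g = values.shape
    return DetectionMatrix(
        values=values,
        cell_ids=np.array([f"cell{i}" for i in range(n)], dtype=object),
        feature_ids=np.array([f"gene{j}" for j in range(g)], dtype=object),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_counts(rng):
    """50 cells x 20 genes of Poisson counts with gene-specific rates."""
    lam = rng.uniform(0.2, 8.0, size=20)
    return make_counts(rng.poisson(lam, size=(50, 20)))
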