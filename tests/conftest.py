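import numpy as np
import pytest

from bedwars import (
    BulkMatrix,
    Hyperparameters,
    ProportionMatrix,
    SignatureMatrix,
)


def make_bulk(values, prefix_g="g", prefix_s="s"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return BulkMatrix(
        values,
        [f"{prefix_g}{i}" for i in range(values.shape[0])],
        [f"{prefix_s}{i}" for i in range(values.shape[1])],
    )


def make_signature(values, prefix_g="g"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return SignatureMatrix(
        values,
        [f"{prefix_g}{i}" for i in range(values.shape[0])],
        [f"ct{i}" for i in range(values.shape[1])],
    )


def make_proportions(values, prefix_s="s"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return ProportionMatrix(
        values,
        [f"ct{i}" for i in range(values.shape[0])],
        [f"{prefix_s}{i}" for i in range(values.shape[1])],
    )


def random_instance(rng, G=None, C=None, N=None):
    """A random small consistent (X, S, S_ref, W, sigma_c, sigma, alpha)."""
    G = G or int(rng.integers(2, 21))
    C = C or int(rng.integers(2, 5))
    N = N or int(rng.integers(1, 6))
    S_ref = make_signature(np.exp(rng.normal(1.5, 1.0, (G, C))))
    S = make_signature(S_ref.values * np.exp(rng.normal(0, 0.2, (G, C))))
    W = make_proportions(rng.dirichlet(np.ones(C), size=N).T)
    X = make_bulk(np.clip(S.values @ W.values + rng.normal(0, 0.3, (G, N)), 0, None))
    sigma_c = rng.uniform(0.1, 2.0, C)
    sigma = float(rng.uniform(0.2, 3.0))
    alpha = float(rng.uniform(0.5, 29.5))
    return X, S, S_ref, W, sigma_c, sigma, alpha


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)


@pytest.fixture
def hp():
    return Hyperparameters()
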