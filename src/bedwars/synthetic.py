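"""Fully synthetic fixtures with the statistical structure the model assumes.

Generates, from one seed: log-normal true signatures, Dirichlet proportion
columns, Gaussian-noise bulk profiles (the mixture model run forward),
references that deviate from truth exactly as the signature prior expects,
and labeled single-cell matrices whose per-type means recover the true
signatures.  These are test fixtures: they target the model's assumptions,
not scRNA-seq platform realism (no dropout, no library-size structure beyond
a scalar per-cell factor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .benchmark import LabeledSCMatrix
from .model import (
    DEFAULT_VARIANCE_FLOOR,
    BulkMatrix,
    ProportionMatrix,
    SignatureMatrix,
)

__all__ = ["SyntheticSpec", "simulate_truth", "simulate_reference", "simulate_sc"]

logger = logging.getLogger("bedwars")


@dataclass
class SyntheticSpec:
    """Shape and noise parameters of the synthetic generative model.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 300 genes, 4 cell types, 40 bulk samples.  Signatures are
    log-normal (median exp(1.5) ~ 4.5 expression units, log-sd 1 giving a
    realistic RPKM-like dynamic range); proportion columns are
    Dirichlet(alpha/C) with alpha = C, i.e. uniform on the simplex; bulk
    noise sd 0.1 is small relative to typical mixture values (~5-10 units)
    so negative clamping is rare.
    """

    G: int = 300
    C: int = 4
    N: int = 40
    n_cells_per_type: int = 200
    signature_log_mean: float = 1.5
    signature_log_sd: float = 1.0
    dirichlet_alpha: float = 4.0
    bulk_noise_sd: float = 0.1
    ref_deviation_sd_per_type: np.ndarray | None = None
    seed: int = 0
    cell_scale_sd: float = 0.2
    sc_noise_sd: float = 0.1
    v_floor: float = DEFAULT_VARIANCE_FLOOR

    def __post_init__(self) -> None:
        if min(self.G, self.C, self.N, self.n_cells_per_type) < 1:
            raise ValueError("G, C, N and n_cells_per_type must be >= 1")
        for name in ("signature_log_sd", "bulk_noise_sd", "cell_scale_sd",
                     "sc_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")
        if self.ref_deviation_sd_per_type is not None:
            self.ref_deviation_sd_per_type = np.asarray(
                self.ref_deviation_sd_per_type, dtype=float
            )
            if self.ref_deviation_sd_per_type.shape != (self.C,):
                raise ValueError("ref_deviation_sd_per_type must have length C")
            if np.any(self.ref_deviation_sd_per_type < 0):
                raise ValueError("deviation sds must be non-negative")

    def deviation_sds(self) -> np.ndarray:
        if self.ref_deviation_sd_per_type is None:
            return np.full(self.C, 0.05)
        return self.ref_deviation_sd_per_type

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(n)]


def simulate_truth(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[SignatureMatrix, ProportionMatrix, BulkMatrix]:
    """Draw true signatures, proportions and the resulting noisy bulk matrix."""
    rng = rng if rng is not None else spec.rng()
    S = np.exp(
        rng.normal(spec.signature_log_mean, spec.signature_log_sd, (spec.G, spec.C))
    )
    conc = np.full(spec.C, spec.dirichlet_alpha / spec.C)
    W = rng.dirichlet(conc, size=spec.N).T
    X = S @ W + rng.normal(0.0, spec.bulk_noise_sd, (spec.G, spec.N))
    n_neg = int((X < 0).sum())
    if n_neg:
        logger.info("clamping %d negative bulk entries (%.3f%%) to zero",
                    n_neg, 100 * n_neg / X.size)
        X = np.clip(X, 0.0, None)
    cts = _ids("ct", spec.C)
    return (
        SignatureMatrix(S, _ids("g", spec.G), cts),
        ProportionMatrix(W, cts, _ids("s", spec.N)),
        BulkMatrix(X, _ids("g", spec.G), _ids("s", spec.N)),
    )


def simulate_reference(
    S_true: SignatureMatrix,
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> SignatureMatrix:
    """Reference signatures deviating from truth as the model prior expects.

    log S_ref = log S_true + Normal(0, sd_c * sqrt(max(log S_true, v_floor))),
    i.e. the model's deviation structure with its direction inverted so that
    tests hold a known truth.
    """
    rng = rng if rng is not None else spec.rng()
    if np.any(S_true.values <= 0):
        raise ValueError("true signature entries must be strictly positive")
    log_s = np.log(S_true.values)
    sd = spec.deviation_sds()[np.newaxis, :] * np.sqrt(
        np.maximum(log_s, spec.v_floor)
    )
    log_ref = log_s + rng.normal(0.0, 1.0, size=log_s.shape) * sd
    return SignatureMatrix(
        np.exp(log_ref), list(S_true.gene_ids), list(S_true.cell_types)
    )


def simulate_sc(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    S_true: SignatureMatrix | None = None,
) -> LabeledSCMatrix:
    """Labeled single-cell matrix around given (or freshly drawn) signatures.

    Each cell of type c is the type's true signature times a gamma per-cell
    scaling (mean 1, sd ``cell_scale_sd``) plus half-normal noise of scale
    ``sc_noise_sd``; per-type means converge to a scaled true signature.
    """
    rng = rng if rng is not None else spec.rng()
    if S_true is None:
        S_true, _, _ = simulate_truth(spec, rng)
    n = spec.n_cells_per_type
    cols, labels = [], []
    for j, ct in enumerate(S_true.cell_types):
        base = S_true.values[:, j]
        if spec.cell_scale_sd > 0:
            shape = 1.0 / spec.cell_scale_sd**2
            scales = rng.gamma(shape, 1.0 / shape, size=n)
        else:
            scales = np.ones(n)
        noise = (
            np.abs(rng.normal(0.0, spec.sc_noise_sd, size=(len(base), n)))
            if spec.sc_noise_sd > 0
            else 0.0
        )
        cols.append(base[:, None] * scales[None, :] + noise)
        labels.extend([ct] * n)
    values = np.concatenate(cols, axis=1)
    return LabeledSCMatrix(
        values=values,
        gene_ids=list(S_true.gene_ids),
        cell_ids=_ids("cell", values.shape[1]),
        cell_labels=labels,
    )
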