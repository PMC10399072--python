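"""Probabilistic model for bulk expression deconvolution.

The bulk expression matrix X (genes x samples, linear scale) is modelled as a
noisy mixture of per-cell-type "true" signatures S mixed at per-sample
proportions W:

    X = S W + E,    E_gn ~ Normal(0, sigma)   (sigma is a standard deviation)

The true signatures are latent and tied to a user-supplied reference signature
S_ref through a log-scale Gaussian prior whose variance grows with reference
expression,

    log S_gc ~ Normal(log S_ref_gc, sigma_c^2 * log S_ref_gc),

with a cell-type-specific deviation scale sigma_c, so that more abundant genes
are allowed to deviate more and some cell types may be globally noisier than
others.  Proportion columns carry a Dirichlet(alpha * w0) prior; sigma_c and
sigma carry Half-Cauchy priors and alpha a uniform prior.

All densities here are pure functions of in-memory matrices; natural
logarithms are used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "BulkMatrix",
    "SignatureMatrix",
    "ProportionMatrix",
    "Hyperparameters",
    "ChainState",
    "DEFAULT_VARIANCE_FLOOR",
    "log_likelihood",
    "log_prior_signature",
    "log_prior_proportions",
    "log_prior_hyper",
    "log_posterior",
    "cell_type_component",
    "half_cauchy_logpdf",
    "signature_variance_multiplier",
]

#: Floor applied to the variance multiplier log(S_ref_gc) of the signature
#: prior.  Eq-style variances sigma_c^2 * log(S_ref) are non-positive for
#: reference values <= 1; the floor keeps the prior proper for low-expression
#: genes without affecting high-expression behaviour.
DEFAULT_VARIANCE_FLOOR = 0.01


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} identifiers")
    return ids


@dataclass
class BulkMatrix:
    """Non-negative bulk expression, genes x samples, linear scale."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("bulk matrix must be 2-D (genes x samples)")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.any(self.values < 0):
            raise ValueError("bulk expression must be non-negative")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SignatureMatrix:
    """Per-cell-type expression profiles, genes x cell types, linear scale."""

    values: np.ndarray
    gene_ids: list[str]
    cell_types: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("signature matrix must be 2-D (genes x cell types)")
        if self.values.shape != (len(self.gene_ids), len(self.cell_types)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_types)} cell types"
            )
        if np.any(self.values < 0):
            raise ValueError("signature expression must be non-negative")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.cell_types = _check_unique(self.cell_types, "cell type")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cell_types(self) -> int:
        return self.values.shape[1]

    def column(self, cell_type: str) -> np.ndarray:
        try:
            j = self.cell_types.index(cell_type)
        except ValueError:
            raise KeyError(f"unknown cell type {cell_type!r}") from None
        return self.values[:, j]


@dataclass
class ProportionMatrix:
    """Cell-type proportions, cell types x samples; columns on the simplex."""

    values: np.ndarray
    cell_types: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("proportion matrix must be 2-D (cell types x samples)")
        if self.values.shape != (len(self.cell_types), len(self.sample_ids)):
            raise ValueError("shape inconsistent with labels")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("proportions must lie in [0, 1]")
        col_sums = self.values.sum(axis=0)
        if not np.allclose(col_sums, 1.0, atol=1e-9):
            raise ValueError("proportion columns must sum to 1 (tolerance 1e-9)")
        self.cell_types = _check_unique(self.cell_types, "cell type")
        self.sample_ids = _check_unique(self.sample_ids, "sample")

    @property
    def n_cell_types(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row(self, cell_type: str) -> np.ndarray:
        try:
            i = self.cell_types.index(cell_type)
        except ValueError:
            raise KeyError(f"unknown cell type {cell_type!r}") from None
        return self.values[i]


@dataclass
class Hyperparameters:
    """Fixed hyperparameters of the model priors.

    beta_s : Half-Cauchy scale of the per-cell-type signature deviation
        scales sigma_c (default 1).
    beta_b : Half-Cauchy scale of the bulk noise standard deviation sigma
        (default 5).
    alpha_min, alpha_max : bounds of the uniform prior on the Dirichlet
        concentration alpha (defaults 0 and 30).
    w0 : Dirichlet mean, a C-dimensional probability vector; ``None`` means
        uniform 1/C, resolved once the number of cell types is known.
    v_floor : floor on the signature-prior variance multiplier log(S_ref).
    """

    beta_s: float = 1.0
    beta_b: float = 5.0
    alpha_min: float = 0.0
    alpha_max: float = 30.0
    w0: np.ndarray | None = None
    v_floor: float = DEFAULT_VARIANCE_FLOOR

    def __post_init__(self) -> None:
        if self.beta_s <= 0 or self.beta_b <= 0:
            raise ValueError("Half-Cauchy scales must be positive")
        if not self.alpha_min < self.alpha_max:
            raise ValueError("alpha_min must be below alpha_max")
        if self.w0 is not None:
            self.w0 = np.asarray(self.w0, dtype=float)
            if np.any(self.w0 <= 0) or not math.isclose(
                float(self.w0.sum()), 1.0, abs_tol=1e-9
            ):
                raise ValueError("w0 must be a strictly positive probability vector")

    def resolve_w0(self, n_cell_types: int) -> np.ndarray:
        if self.w0 is None:
            return np.full(n_cell_types, 1.0 / n_cell_types)
        if self.w0.shape != (n_cell_types,):
            raise ValueError("w0 length does not match the number of cell types")
        return self.w0


@dataclass
class ChainState:
    """Full parameter set of one MH chain: {S, W, {sigma_c}, sigma, alpha}."""

    S: SignatureMatrix
    W: ProportionMatrix
    sigma_c: np.ndarray
    sigma: float
    alpha: float

    def __post_init__(self) -> None:
        self.sigma_c = np.asarray(self.sigma_c, dtype=float)
        if self.sigma_c.shape != (self.S.n_cell_types,):
            raise ValueError("sigma_c length must equal the number of cell types")
        if np.any(self.sigma_c <= 0):
            raise ValueError("all sigma_c must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if np.any(self.S.values <= 0):
            raise ValueError("chain signature entries must be strictly positive")


# ---------------------------------------------------------------------------
# densities


def _require_shapes(X: BulkMatrix, S: SignatureMatrix, W: ProportionMatrix) -> None:
    if X.gene_ids != S.gene_ids:
        raise ValueError("bulk and signature gene sets/orderings differ")
    if S.cell_types != W.cell_types:
        raise ValueError("signature and proportion cell-type orderings differ")
    if X.sample_ids != W.sample_ids:
        raise ValueError("bulk and proportion sample orderings differ")


def log_likelihood(
    X: BulkMatrix, S: SignatureMatrix, W: ProportionMatrix, sigma: float
) -> float:
    """Gaussian log-likelihood of the bulk matrix under the mixture model.

    Sum over genes g and samples n of log Normal(X_gn | (S W)_gn, sigma),
    with ``sigma`` the shared noise standard deviation.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    _require_shapes(X, S, W)
    resid = X.values - S.values @ W.values
    n_terms = resid.size
    return float(
        -0.5 * n_terms * math.log(2.0 * math.pi)
        - n_terms * math.log(sigma)
        - 0.5 * float(np.sum(resid**2)) / sigma**2
    )


def signature_variance_multiplier(
    S_ref: SignatureMatrix, v_floor: float = DEFAULT_VARIANCE_FLOOR
) -> np.ndarray:
    """Per-entry variance multiplier max(log S_ref, v_floor) of the signature prior."""
    if np.any(S_ref.values <= 0):
        raise ValueError("reference signature entries must be strictly positive")
    return np.maximum(np.log(S_ref.values), v_floor)


def log_prior_signature(
    S: SignatureMatrix,
    S_ref: SignatureMatrix,
    sigma_c: np.ndarray,
    v_floor: float = DEFAULT_VARIANCE_FLOOR,
) -> float:
    """Log-density of the true signatures around the reference.

    Each log S_gc is Normal with mean log S_ref_gc and variance
    sigma_c^2 * max(log S_ref_gc, v_floor).
    """
    sigma_c = np.asarray(sigma_c, dtype=float)
    if np.any(sigma_c <= 0):
        raise ValueError("all sigma_c must be positive")
    if S.gene_ids != S_ref.gene_ids or S.cell_types != S_ref.cell_types:
        raise ValueError("S and S_ref must share gene and cell-type orderings")
    if np.any(S.values <= 0):
        raise ValueError("signature entries must be strictly positive")
    vmult = signature_variance_multiplier(S_ref, v_floor)
    var = sigma_c[np.newaxis, :] ** 2 * vmult
    dev = np.log(S.values) - np.log(S_ref.values)
    return float(
        np.sum(-0.5 * np.log(2.0 * math.pi * var) - dev**2 / (2.0 * var))
    )


def log_prior_proportions(
    W: ProportionMatrix, alpha: float, w0: np.ndarray
) -> float:
    """Sum over samples of the Dirichlet(alpha * w0) log-density of W columns."""
    w0 = np.asarray(w0, dtype=float)
    conc = alpha * w0
    if np.any(conc <= 0):
        raise ValueError("concentration alpha * w0 must be strictly positive")
    if w0.shape != (W.n_cell_types,):
        raise ValueError("w0 length does not match W")
    vals = W.values
    # boundary columns carry zero posterior mass: any zero entry sends the
    # log-density to -inf except in the conc == 1 case where the term vanishes
    if np.any((vals == 0) & (conc[:, None] != 1.0)):
        return -math.inf
    norm = gammaln(conc.sum()) - gammaln(conc).sum()
    with np.errstate(divide="ignore"):
        logw = np.log(vals)
    terms = (conc[:, None] - 1.0) * logw
    terms = np.where(conc[:, None] == 1.0, 0.0, terms)
    return W.n_samples * float(norm) + float(np.sum(terms))


def half_cauchy_logpdf(x: np.ndarray | float, beta: float) -> np.ndarray | float:
    """Log-density of the Half-Cauchy distribution with scale ``beta`` on x > 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x > 0,
        math.log(2.0 / math.pi) - math.log(beta) - np.log1p((x / beta) ** 2),
        -math.inf,
    )
    return float(out) if out.ndim == 0 else out


def log_prior_hyper(state: ChainState, hp: Hyperparameters) -> float:
    """Log-density of the hyperpriors: Half-Cauchy on sigma_c and sigma,
    uniform on alpha."""
    total = float(np.sum(half_cauchy_logpdf(state.sigma_c, hp.beta_s)))
    total += float(half_cauchy_logpdf(state.sigma, hp.beta_b))
    if hp.alpha_min <= state.alpha <= hp.alpha_max:
        total -= math.log(hp.alpha_max - hp.alpha_min)
    else:
        return -math.inf
    return total


def log_posterior(
    X: BulkMatrix, state: ChainState, S_ref: SignatureMatrix, hp: Hyperparameters
) -> float:
    """Joint log-posterior: likelihood + signature, proportion and hyper priors."""
    w0 = hp.resolve_w0(state.W.n_cell_types)
    parts = (
        log_likelihood(X, state.S, state.W, state.sigma),
        log_prior_signature(state.S, S_ref, state.sigma_c, hp.v_floor),
        log_prior_proportions(state.W, state.alpha, w0),
        log_prior_hyper(state, hp),
    )
    if any(p == -math.inf for p in parts):
        return -math.inf
    return float(sum(parts))


def cell_type_component(
    S_hat: SignatureMatrix, W_hat: ProportionMatrix, cell_type: str
) -> BulkMatrix:
    """Reconstructed bulk contribution of one cell type.

    Entry (g, n) is the inferred signature value of gene g in ``cell_type``
    times the inferred proportion of that cell type in sample n; components
    summed over all cell types reproduce S_hat @ W_hat exactly.
    """
    s = S_hat.column(cell_type)
    w = W_hat.row(cell_type)
    return BulkMatrix(
        values=np.outer(s, w),
        gene_ids=list(S_hat.gene_ids),
        sample_ids=list(W_hat.sample_ids),
    )
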