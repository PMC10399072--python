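"""Multi-chain Metropolis-Hastings inference for the deconvolution model.

The posterior over {S, W, {sigma_c}, sigma, alpha} is explored by block-wise
random-walk MH.  Parameterization: signatures are sampled as z = log S (the
signature prior is a Gaussian density on log S, so no Jacobian appears in the
z-space target); proportion columns via the additive log-ratio transform of
the simplex (inverse-ALR Jacobian prod_c w_c included); sigma, sigma_c and
alpha via log-scale random walks (log-walk Jacobian x'/x included, alpha
reflected at its uniform bounds in log space).

Blocks are updated per sweep in the fixed order S, W, sigma_c, sigma, alpha.
The S and W targets factorize over genes and samples respectively given the
rest of the state, so those blocks accept or reject each gene row / sample
column independently, which keeps acceptance usable at realistic dimensions.
Step sizes are adapted during burn-in only (Robbins-Monro toward ~0.35
acceptance) and frozen afterwards.

Point estimates follow the best-chain rule: every chain accumulates running
means of all parameters over its post-burn-in sweeps, chains are scored by
the mean squared reconstruction error of the bulk matrix restricted to
marker genes (genes with at least ``marker_fold``-fold higher reference
expression in one cell type than in every other), and the minimizing chain's
averages are reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln

from .model import (
    BulkMatrix,
    ChainState,
    Hyperparameters,
    ProportionMatrix,
    SignatureMatrix,
    half_cauchy_logpdf,
    log_posterior,
    signature_variance_multiplier,
)

__all__ = [
    "SamplerConfig",
    "ChainTrace",
    "DeconvolutionResult",
    "select_markers",
    "init_chain",
    "mh_step",
    "run_chain",
    "score_chain",
    "deconvolve",
]

_BLOCKS = ("S", "W", "sigma_c", "sigma", "alpha")
_ADAPT_TARGET = 0.35  # middle of the 0.25-0.45 acceptance window


@dataclass
class SamplerConfig:
    """Settings of the multi-chain MH run.

    ``n_chains`` defaults to the benchmarking-scale 150; desk-scale analyses
    typically override it downward.  ``proposal_scales`` are initial per-block
    random-walk standard deviations; burn-in adaptation tunes them per chain.
    """

    n_chains: int = 150
    n_iterations: int = 20_000
    burn_in_fraction: float = 0.5
    seed: int = 0
    proposal_scales: dict[str, float] = field(
        default_factory=lambda: {
            "S": 0.05,
            "W": 0.1,
            "sigma_c": 0.2,
            "sigma": 0.1,
            "alpha": 0.3,
        }
    )
    marker_fold: float = 4.0
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 4:
            raise ValueError(
                "n_chains must be at least 4 (the sigma_c initialization "
                "scheme uses four chain groups)"
            )
        if not 0.0 < self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must lie in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")
        if self.marker_fold <= 0:
            raise ValueError("marker_fold must be positive")
        for name in _BLOCKS:
            if self.proposal_scales.get(name, 0.0) < 0:
                raise ValueError(f"proposal scale for block {name} must be >= 0")

    @property
    def burn_in(self) -> int:
        return int(self.n_iterations * self.burn_in_fraction)


@dataclass
class ChainTrace:
    """Post-burn-in running averages of one chain plus its selection score."""

    S_mean: np.ndarray
    W_mean: np.ndarray
    sigma_c_mean: np.ndarray
    sigma_mean: float
    alpha_mean: float
    marker_mse: float
    acceptance_rates: dict[str, float]
    n_kept: int


@dataclass
class DeconvolutionResult:
    """Best-chain point estimates of signatures, proportions and scales."""

    S_hat: SignatureMatrix
    W_hat: ProportionMatrix
    sigma_c_hat: np.ndarray
    sigma_hat: float
    alpha_hat: float
    best_chain_index: int
    chain_scores: np.ndarray
    acceptance_rates: dict[str, float]
    n_genes_used: int
    marker_genes: list[str]


def select_markers(S_ref: SignatureMatrix, fold: float = 4.0) -> list[str]:
    """Genes with at least ``fold``-fold higher reference expression in one
    cell type than in every other (boundary inclusive)."""
    if S_ref.n_cell_types < 2:
        raise ValueError("marker selection requires at least two cell types")
    V = S_ref.values
    out: list[str] = []
    for g in range(V.shape[0]):
        row = V[g]
        top = np.argmax(row)
        rest = np.delete(row, top)
        if np.all(row[top] >= fold * rest):
            out.append(S_ref.gene_ids[g])
    return out


def _sample_half_cauchy(rng: np.random.Generator, beta: float, size=None):
    u = rng.uniform(size=size)
    return beta * np.tan(0.5 * math.pi * u)


def init_chain(
    S_ref: SignatureMatrix,
    hp: Hyperparameters,
    chain_index: int,
    n_chains: int,
    rng: np.random.Generator,
    sample_ids: list[str] | None = None,
) -> ChainState:
    """Initial state of chain ``chain_index`` of ``n_chains``.

    S starts at the reference, W columns at the Dirichlet mean w0, alpha and
    sigma at prior draws.  sigma_c is set by chain group: the first
    4*(n_chains // 4) chains cycle through [0.01], [0.1], [1] and prior
    draws (index mod 4); remainder chains use prior draws.  Without
    ``sample_ids`` the returned W holds a single placeholder column (every
    column is w0 regardless of the number of samples).
    """
    if not 0 <= chain_index < n_chains:
        raise ValueError("chain_index out of range")
    C = S_ref.n_cell_types
    w0 = hp.resolve_w0(C)
    alpha = float(rng.uniform(hp.alpha_min, hp.alpha_max))
    sigma = float(_sample_half_cauchy(rng, hp.beta_b))
    group = chain_index % 4 if chain_index < 4 * (n_chains // 4) else 3
    if group == 0:
        sigma_c = np.full(C, 0.01)
    elif group == 1:
        sigma_c = np.full(C, 0.1)
    elif group == 2:
        sigma_c = np.full(C, 1.0)
    else:
        sigma_c = np.asarray(_sample_half_cauchy(rng, hp.beta_s, size=C))
    ids = sample_ids if sample_ids is not None else ["_init"]
    return ChainState(
        S=SignatureMatrix(
            S_ref.values.copy(), list(S_ref.gene_ids), list(S_ref.cell_types)
        ),
        W=ProportionMatrix(
            np.repeat(w0[:, None], len(ids), axis=1),
            list(S_ref.cell_types),
            list(ids),
        ),
        sigma_c=sigma_c,
        sigma=sigma,
        alpha=alpha,
    )


class _ChainRunner:
    """Mutable chain state with cached sufficient statistics for fast sweeps."""

    def __init__(
        self,
        X: BulkMatrix,
        S_ref: SignatureMatrix,
        hp: Hyperparameters,
        config: SamplerConfig,
        state: ChainState,
    ) -> None:
        if X.gene_ids != S_ref.gene_ids:
            raise ValueError("bulk and reference gene orderings differ")
        self.X = X.values
        self.G, self.N = self.X.shape
        self.C = S_ref.n_cell_types
        self.hp = hp
        self.mu = np.log(S_ref.values)  # prior means of z = log S
        self.vmult = signature_variance_multiplier(S_ref, hp.v_floor)
        self.w0 = hp.resolve_w0(self.C)

        self.Z = np.log(state.S.values)
        self.S = state.S.values.copy()
        W = state.W.values
        if W.shape[1] != self.N:
            W = np.repeat(W[:, :1], self.N, axis=1)
        self.W = W.copy()
        self.logW = np.log(self.W)
        self.sigma_c_val = state.sigma_c.astype(float).copy()
        self.sigma_val = float(state.sigma)
        self.alpha = float(state.alpha)
        self.M = self.S @ self.W
        self.R = self.X - self.M
        self.steps = {k: float(v) for k, v in config.proposal_scales.items()}
        self._acc_sums = {k: 0.0 for k in _BLOCKS}
        self._acc_n = 0

    # -- block updates -----------------------------------------------------

    def _update_S(self, rng: np.random.Generator) -> float:
        step = self.steps["S"]
        if step == 0.0:  # degenerate proposal: identity move, always accepted
            return 1.0
        eps = rng.normal(0.0, 1.0, size=(self.G, self.C)) * step
        u = rng.uniform(size=self.G)
        Zp = self.Z + eps
        Sp = np.exp(Zp)
        D = (Sp - self.S) @ self.W
        Rp = self.R - D
        sigma2 = self.sigma_val**2
        dlik = -0.5 * ((Rp**2).sum(axis=1) - (self.R**2).sum(axis=1)) / sigma2
        var = (self.sigma_c_val**2)[None, :] * self.vmult
        dprior = (
            ((self.Z - self.mu) ** 2 - (Zp - self.mu) ** 2) / (2.0 * var)
        ).sum(axis=1)
        delta = dlik + dprior
        acc = (delta >= 0) | (np.log(u) < delta)
        if np.any(acc):
            self.Z[acc] = Zp[acc]
            self.S[acc] = Sp[acc]
            self.R[acc] = Rp[acc]
        return float(acc.mean())

    def _update_W(self, rng: np.random.Generator) -> float:
        step = self.steps["W"]
        if step == 0.0:
            return 1.0
        eps = rng.normal(0.0, 1.0, size=(self.C - 1, self.N)) * step
        u = rng.uniform(size=self.N)
        Y = self.logW[:-1] - self.logW[-1]  # ALR coordinates
        Yp = Y + eps
        A = np.vstack([Yp, np.zeros((1, self.N))])
        A -= A.max(axis=0, keepdims=True)
        E = np.exp(A)
        Wp = E / E.sum(axis=0, keepdims=True)
        logWp = np.log(Wp)
        Mp = self.S @ Wp
        Rp = self.X - Mp
        sigma2 = self.sigma_val**2
        dlik = -0.5 * ((Rp**2).sum(axis=0) - (self.R**2).sum(axis=0)) / sigma2
        # Dirichlet prior (conc - 1) terms plus the inverse-ALR Jacobian
        # prod_c w_c collapse to sum_c conc_c * d log w_c
        conc = self.alpha * self.w0
        dprior = (conc[:, None] * (logWp - self.logW)).sum(axis=0)
        delta = dlik + dprior
        acc = (delta >= 0) | (np.log(u) < delta)
        if np.any(acc):
            self.W[:, acc] = Wp[:, acc]
            self.logW[:, acc] = logWp[:, acc]
            self.M[:, acc] = Mp[:, acc]
            self.R[:, acc] = Rp[:, acc]
        return float(acc.mean())

    def _update_sigma_c(self, rng: np.random.Generator) -> float:
        step = self.steps["sigma_c"]
        if step == 0.0:
            return 1.0
        eps = rng.normal(0.0, 1.0, size=self.C) * step
        u = rng.uniform(size=self.C)
        lsc = np.log(self.sigma_c_val)
        lscp = lsc + eps
        q = (((self.Z - self.mu) ** 2) / self.vmult).sum(axis=0)
        inv2 = np.exp(-2.0 * lscp) - np.exp(-2.0 * lsc)
        delta = (
            -self.G * (lscp - lsc)
            - 0.5 * q * inv2
            + half_cauchy_logpdf(np.exp(lscp), self.hp.beta_s)
            - half_cauchy_logpdf(np.exp(lsc), self.hp.beta_s)
            + (lscp - lsc)  # log-walk Jacobian
        )
        acc = (delta >= 0) | (np.log(u) < delta)
        self.sigma_c_val[acc] = np.exp(lscp[acc])
        return float(acc.mean())

    def _update_sigma(self, rng: np.random.Generator) -> float:
        step = self.steps["sigma"]
        if step == 0.0:
            return 1.0
        ls = math.log(self.sigma_val)
        lsp = ls + rng.normal(0.0, 1.0) * step
        u = rng.uniform()
        ssr = float((self.R**2).sum())
        delta = (
            -self.G * self.N * (lsp - ls)
            - 0.5 * ssr * (math.exp(-2.0 * lsp) - self.sigma_val**-2)
            + half_cauchy_logpdf(math.exp(lsp), self.hp.beta_b)
            - half_cauchy_logpdf(self.sigma_val, self.hp.beta_b)
            + (lsp - ls)
        )
        acc = delta >= 0 or math.log(u) < delta
        if acc:
            self.sigma_val = math.exp(lsp)
        return float(acc)

    def _update_alpha(self, rng: np.random.Generator) -> float:
        step = self.steps["alpha"]
        if step == 0.0:
            return 1.0
        la = math.log(self.alpha)
        lap = la + rng.normal(0.0, 1.0) * step
        u = rng.uniform()
        # reflect at the uniform bounds in log space (alpha_min = 0 maps to
        # -inf, needing no lower reflection)
        lo = -math.inf if self.hp.alpha_min <= 0 else math.log(self.hp.alpha_min)
        hi = math.log(self.hp.alpha_max)
        for _ in range(64):
            if lap > hi:
                lap = 2.0 * hi - lap
            elif lap < lo:
                lap = 2.0 * lo - lap
            else:
                break
        ap = math.exp(lap)
        T = self.logW.sum(axis=1)
        conc, concp = self.alpha * self.w0, ap * self.w0

        def _norm(c: np.ndarray) -> float:
            return float(gammaln(c.sum()) - gammaln(c).sum())

        delta = (
            self.N * (_norm(concp) - _norm(conc))
            + float(((concp - conc) * T).sum())
            + (lap - la)
        )
        acc = delta >= 0 or math.log(u) < delta
        if acc:
            self.alpha = ap
        return float(acc)

    # -- sweep & adaptation ------------------------------------------------

    def sweep(self, rng: np.random.Generator) -> dict[str, float]:
        rates = {"S": self._update_S(rng)}
        rates["W"] = self._update_W(rng) if self.C > 1 else 1.0
        rates["sigma_c"] = self._update_sigma_c(rng)
        rates["sigma"] = self._update_sigma(rng)
        rates["alpha"] = self._update_alpha(rng)
        return rates

    def adapt(self, rates: dict[str, float], t: int) -> None:
        gamma = (t + 1) ** -0.6
        for name, rate in rates.items():
            if self.steps.get(name, 0.0) > 0:
                self.steps[name] *= math.exp(gamma * (rate - _ADAPT_TARGET))

    def record_acceptance(self, rates: dict[str, float]) -> None:
        for name, rate in rates.items():
            self._acc_sums[name] += rate
        self._acc_n += 1

    def acceptance_rates(self) -> dict[str, float]:
        n = max(self._acc_n, 1)
        return {k: v / n for k, v in self._acc_sums.items()}

    def to_state(self, sample_ids: list[str], gene_ids: list[str],
                 cell_types: list[str]) -> ChainState:
        return ChainState(
            S=SignatureMatrix(self.S.copy(), list(gene_ids), list(cell_types)),
            W=ProportionMatrix(self.W.copy(), list(cell_types), list(sample_ids)),
            sigma_c=self.sigma_c_val.copy(),
            sigma=self.sigma_val,
            alpha=self.alpha,
        )


def mh_step(
    state: ChainState,
    X: BulkMatrix,
    S_ref: SignatureMatrix,
    hp: Hyperparameters,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> tuple[ChainState, dict[str, float]]:
    """One block-wise MH sweep from ``state``; returns the new state and the
    per-block acceptance indicator (fraction of accepted sub-blocks)."""
    if not math.isfinite(log_posterior(X, state, S_ref, hp)):
        raise ValueError("starting state has non-finite log-posterior")
    runner = _ChainRunner(X, S_ref, hp, config, state)
    rates = runner.sweep(rng)
    new = runner.to_state(X.sample_ids, X.gene_ids, S_ref.cell_types)
    return new, rates


def score_chain(
    X: BulkMatrix,
    S_hat: SignatureMatrix,
    W_hat: ProportionMatrix,
    markers: list[str],
) -> float:
    """Mean squared bulk reconstruction error restricted to marker genes."""
    if not markers:
        raise ValueError(
            "empty marker set: no gene exceeds the fold threshold in a single "
            "cell type; lower marker_fold"
        )
    index = {g: i for i, g in enumerate(X.gene_ids)}
    try:
        rows = np.array([index[g] for g in markers])
    except KeyError as exc:
        raise ValueError(f"marker gene {exc} absent from the bulk matrix") from exc
    resid = X.values[rows] - (S_hat.values @ W_hat.values)[rows]
    return float(np.mean(resid**2))


def chain_rng(seed: int, chain_index: int) -> np.random.Generator:
    """Independent, order-insensitive RNG stream for one chain."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(chain_index,)))


def run_chain(
    X: BulkMatrix,
    S_ref: SignatureMatrix,
    hp: Hyperparameters,
    config: SamplerConfig,
    chain_index: int,
    rng: np.random.Generator,
    markers: list[str] | None = None,
) -> ChainTrace:
    """Run one chain for ``config.n_iterations`` sweeps and return running
    averages of all parameters over the post-burn-in sweeps."""
    state = init_chain(
        S_ref, hp, chain_index, config.n_chains, rng, sample_ids=X.sample_ids
    )
    runner = _ChainRunner(X, S_ref, hp, config, state)
    burn_in = config.burn_in
    S_acc = np.zeros_like(runner.S)
    W_acc = np.zeros_like(runner.W)
    sc_acc = np.zeros(runner.C)
    s_acc = 0.0
    a_acc = 0.0
    kept = 0
    for t in range(config.n_iterations):
        rates = runner.sweep(rng)
        if t < burn_in:
            if config.adapt:
                runner.adapt(rates, t)
        else:
            runner.record_acceptance(rates)
            S_acc += runner.S
            W_acc += runner.W
            sc_acc += runner.sigma_c_val
            s_acc += runner.sigma_val
            a_acc += runner.alpha
            kept += 1
    S_mean = S_acc / kept
    W_mean = W_acc / kept
    if markers is None:
        if runner.C > 1:
            markers = select_markers(S_ref, config.marker_fold)
        else:
            markers = list(X.gene_ids)
    mse = score_chain(
        X,
        SignatureMatrix(S_mean, list(X.gene_ids), list(S_ref.cell_types)),
        ProportionMatrix(
            W_mean / W_mean.sum(axis=0, keepdims=True),
            list(S_ref.cell_types),
            list(X.sample_ids),
        ),
        markers,
    )
    return ChainTrace(
        S_mean=S_mean,
        W_mean=W_mean,
        sigma_c_mean=sc_acc / kept,
        sigma_mean=s_acc / kept,
        alpha_mean=a_acc / kept,
        marker_mse=mse,
        acceptance_rates=runner.acceptance_rates(),
        n_kept=kept,
    )


def deconvolve(
    X: BulkMatrix,
    S_ref: SignatureMatrix,
    hp: Hyperparameters | None = None,
    config: SamplerConfig | None = None,
) -> DeconvolutionResult:
    """Full multi-chain deconvolution of ``X`` against reference ``S_ref``.

    Genes are harmonized (intersection, zero filtering) before inference;
    chains run independently on per-index RNG streams, the chain minimizing
    the marker-restricted reconstruction MSE supplies the point estimates.
    """
    from .io import harmonize

    hp = hp or Hyperparameters()
    config = config or SamplerConfig()
    X, S_ref = harmonize(X, S_ref)
    C = S_ref.n_cell_types
    if X.n_samples < 4 * C:
        warnings.warn(
            f"only {X.n_samples} bulk samples for {C} cell types; at least "
            "4x the number of cell types is recommended",
            stacklevel=2,
        )
    markers = select_markers(S_ref, config.marker_fold) if C > 1 else list(X.gene_ids)
    traces: list[ChainTrace] = []
    for idx in range(config.n_chains):
        rng = chain_rng(config.seed, idx)
        traces.append(run_chain(X, S_ref, hp, config, idx, rng, markers))
    scores = np.array([t.marker_mse for t in traces])
    if not np.any(np.isfinite(scores)):
        raise RuntimeError("all chains produced non-finite scores")
    best = int(np.argmin(scores))
    tb = traces[best]
    W_hat = tb.W_mean / tb.W_mean.sum(axis=0, keepdims=True)
    return DeconvolutionResult(
        S_hat=SignatureMatrix(tb.S_mean, list(X.gene_ids), list(S_ref.cell_types)),
        W_hat=ProportionMatrix(W_hat, list(S_ref.cell_types), list(X.sample_ids)),
        sigma_c_hat=tb.sigma_c_mean,
        sigma_hat=tb.sigma_mean,
        alpha_hat=tb.alpha_mean,
        best_chain_index=best,
        chain_scores=scores,
        acceptance_rates=tb.acceptance_rates,
        n_genes_used=X.n_genes,
        marker_genes=markers,
    )
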