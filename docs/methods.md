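# Methods

## Model

Bulk expression profiles are modelled as noisy linear mixtures of cell-type
signatures:

    X = S W + E,        E_gn ~ Normal(0, σ)

with X the G × N bulk matrix (linear scale, RPKM/FPKM/CPM-like), S the G × C
matrix of *true* per-cell-type signatures, W the C × N proportion matrix
whose columns lie on the probability simplex, and a single noise standard
deviation σ shared by all genes and samples. σ is treated as a standard
deviation, consistent with placing a Half-Cauchy scale prior on it.

The distinguishing assumption is that the true signatures are latent and
anchored to a user-supplied reference S^r through a log-scale Gaussian
prior whose variance grows with reference abundance:

    log S_gc ~ Normal( log S^r_gc ,  σ_c² · log S^r_gc )

so highly expressed genes are allowed to drift further from the reference,
and each cell type has its own global deviation scale σ_c. Natural
logarithms are used throughout; the Gaussian algebra is base-free once the
base is fixed, and e is the convention everywhere else in the package.

Remaining priors: W columns are Dirichlet(α·W₀) with W₀ = [1/C] by default;
σ_c ~ HalfCauchy(β_s), σ ~ HalfCauchy(β_b), α ~ Uniform(α_min, α_max).
Defaults β_s = 1, β_b = 5, α ∈ [0, 30].

Two numerical guards:

* **Variance floor.** The prior variance multiplier log S^r_gc is
  non-positive whenever S^r_gc ≤ 1, which would make the prior improper for
  low-expression genes. The multiplier is floored at `v_floor = 0.01`
  (configurable on `Hyperparameters`); genes well above one expression unit
  are unaffected.
* **Zero filtering.** Genes with a zero in any reference column are removed
  before modelling (the log-scale prior is undefined there); an optional
  strict mode also removes genes with bulk zeros. Counts are logged.

## Inference

Maximum-a-posteriori-style estimation by multi-chain random-walk
Metropolis–Hastings. Per sweep, five blocks are updated in fixed order —
S, W, {σ_c}, σ, α — each with a proposal that keeps the state in-domain:

* **S** is sampled in z = log S coordinates. The signature prior is already
  a density on log S, so a symmetric Gaussian step in z needs no Jacobian;
  the likelihood term is evaluated at S = exp(z). Because both the
  likelihood and the prior factorize over genes given the rest of the
  state, each gene row is accepted or rejected independently, which keeps
  acceptance rates usable at realistic G.
* **W** columns move under a Gaussian step in additive log-ratio
  coordinates, with the inverse-ALR Jacobian Π_c w_c in the ratio; columns
  accept independently (the likelihood factorizes over samples, the
  Dirichlet prior over columns).
* **σ_c, σ, α** use log-scale random walks with the x′/x Jacobian; α is
  reflected at its uniform bounds in log space, preserving proposal
  symmetry.

Step sizes adapt during burn-in only (Robbins–Monro toward ≈ 0.35
acceptance, inside the standard 0.25–0.45 window) and are frozen afterwards
so the post-burn-in kernel is a valid fixed MH kernel.

**Initialization.** Every chain starts at S = S^r and W columns = W₀, with
α, σ drawn from their priors. σ_c is set by chain group (index mod 4):
[0.01], [0.1], [1.0], or Half-Cauchy(β_s) draws; when the chain count is
not divisible by four the remainder chains use prior draws.

**Point estimates and chain selection.** Each chain accumulates running
means of all parameters over post-burn-in sweeps (S averaged on the linear
scale; averages of simplex points remain on the simplex). Chains are scored
by the mean squared error between X and Ŝ·Ŵ restricted to marker genes —
genes with at least four-fold higher reference expression in one cell type
than in every other (boundary inclusive) — and the minimizing chain's
averages are reported. The procedure averages posterior samples even though
its intent is MAP-style point estimation; the package follows the procedure.

**Reproducibility.** One root seed; each chain draws from an independent
stream keyed by chain index (`SeedSequence(seed, spawn_key=(index,))`), so
serial and any parallel execution order give bit-identical results.

Defaults: 150 chains (benchmarking scale), 20,000 sweeps, burn-in fraction
0.5 — iteration counts and proposal families are implementation choices, so
they are exposed on `SamplerConfig` and deliberately conservative. A
warning is emitted when N < 4·C samples are provided.

## Signature perturbation (noise levels)

Benchmarks need references that diverge from the truth by a controlled
amount. Per cell type, on log-transformed values:

1. genes are sorted by their *true*-signature value and split into
   consecutive equal-frequency bins of `bin_size` genes (the last bin
   absorbs any remainder; ties break by original gene order);
2. within each bin, reference values x are replaced by
   mean(x) + (σ/sd(x))·(x − mean(x)): the bin mean is preserved exactly and
   the bin standard deviation becomes σ (sample sd, ddof = 1 — the
   convention is unstated in the field description, so the package fixes it
   and uses the same convention in its invariant tests);
3. (stochastic stage) within each outer bin, genes are re-sorted by their
   stage-one value, grouped into sub-bins of four, and values shuffled
   uniformly within each sub-bin — outer-bin multisets are untouched.

Noise level NL-k uses σ = 1 + 0.25·(k−1), k = 1..6; each level yields 11
variants (stage one, plus ten independent shuffles). A bin whose reference
values are all equal cannot be inflated by scaling; it collapses to its
mean with a warning. Cell types can be exempted from perturbation
(`NoiseConfig.exempt_cell_types`), mirroring the practice of leaving
already-poorly-matched cell types untouched.

## Pseudo-bulk recipes

* **Composition-controlled ("pancreas"-style).** Per mixture: the number of
  present types k ~ Uniform{2..K}; k types sampled without replacement;
  weights ~ Uniform[0.05, 1], normalized; 100 cells allocated to types by
  largest-remainder rounding (exact total) and sampled without replacement
  within a type; the profile is the mean of the sampled cells. The recorded
  truth is the continuous normalized weights (realized integer counts are
  stored alongside). Cells may recur across mixtures.
* **Unconstrained ("brain"-style).** Per mixture, 100 cells drawn uniformly
  without replacement from the whole dataset and averaged; truth is the
  realized label fractions (columns sum to one exactly; the largest entry
  absorbs the one-ulp float residue).

Reference signatures from labeled single-cell data are per-type means, with
genes kept only if they exceed one expression unit in at least one type
(strict inequality, matching the "more than one RPKM/FPKM" convention).

## Synthetic fixtures

`SyntheticSpec` drives a generator that runs the model forward: log-normal
true signatures (log-mean 1.5, log-sd 1.0 — a median around 4.5 expression
units with an RPKM-like dynamic range), Dirichlet proportion columns
(concentration α/C with α = C by default, i.e. uniform on the simplex),
Gaussian bulk noise (sd 0.1, small against typical mixture values of 5–10
units so negative clamping is rare and logged), and references generated
*from* the truth by inverting the deviation prior's direction — equivalent
in distribution for the symmetric Gaussian deviations, and necessary for
tests to hold a known truth. Single-cell fixtures multiply a type's
signature by a per-cell gamma factor (mean 1, sd 0.2) and add half-normal
noise; they target the model's assumptions, not platform realism — no
dropout, no count statistics, no library-size structure beyond the scalar
factor — so passing tests certify the estimator under its own model, not
performance on real scRNA-seq.

## Desk-scale study conditions

The recovery and robustness checks (test suite and `scripts/acceptance.py`)
use G = 300 genes, C = 4 cell types, N = 40 samples, 8 chains × 20,000
sweeps, and perturbation bin size 50 (≥ 6 equal-frequency bins at this gene
count; published analyses use 100–300-gene bins at 10–20k genes). Under
these conditions: proportion recovery with the true reference is
near-perfect (mean per-cell-type PCC > 0.99); with shuffled NL-perturbed
references the Bayesian estimates hold PCC ≈ 1 while NNLS with the same
noisy reference degrades (≈ 0.89–0.98 across seeds and levels); inferred
signatures at σ = 1.5 noise are substantially closer to truth (log-scale
PCC ≈ 0.95) than the perturbed reference itself (≈ 0.72).

## Known limitations

* One signature matrix per dataset — no sample-specific signature
  adjustment.
* Gaussian likelihood on the linear scale; no outlier-robust variants.
* Chain selection is by marker-gene reconstruction MSE only; no R-hat or
  other cross-chain convergence diagnostics.
* The NNLS comparator stands in for external deconvolution tools in
  property tests; it is not a reimplementation of any of them.
* CPU implementation; chains are embarrassingly parallel but run serially
  by default.
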