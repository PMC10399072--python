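# bedwars

Bayesian deconvolution of bulk gene-expression profiles that **jointly
estimates cell-type proportions and the cell-type expression signatures
themselves**, instead of trusting a fixed reference.

Reference signatures are usually built from a different dataset than the
bulk samples being deconvolved — different platform, lab, or even species —
so the signatures underlying the bulk data ("true" signatures) deviate from
the reference in ways that wreck fixed-signature methods. This package
models that deviation explicitly and infers both quantities at once, for
anyone benchmarking or applying reference-based deconvolution on bulk
RNA-seq with single-cell-derived signatures.

## Model

With X the G×N bulk matrix, S the latent G×C true signatures, W the C×N
proportions (columns on the simplex):

```
X = S W + E,                E_gn ~ N(0, σ)
log S_gc ~ N( log S^r_gc ,  σ_c² · log S^r_gc )
W_i ~ Dirichlet(α · W₀),    W₀ = [1/C] by default
σ_c ~ HalfCauchy(β_s),  σ ~ HalfCauchy(β_b),  α ~ Unif(α_min, α_max)
```

Each cell type gets its own deviation scale σ_c, and more abundant genes
are allowed to drift further from the reference. Inference is multi-chain
block-wise Metropolis–Hastings; the chain that best reconstructs the bulk
matrix on marker genes (≥ 4-fold higher reference expression in one cell
type than all others) supplies the point estimates as post-burn-in means.
See `docs/methods.md` for the full procedure, parameterizations and
numerical choices.

The package also ships the benchmarking machinery used to study robustness:
controlled two-stage signature perturbation (noise levels NL-1…NL-6,
σ = 1.0…2.25), pseudo-bulk mixture generation with known ground truth,
per-cell-type evaluation metrics (PCC/MAE/RMSE), an NNLS comparator, and a
fully synthetic fixture generator.

## Worked example

```python
import numpy as np
from bedwars import (SyntheticSpec, simulate_truth, simulate_reference,
                     Hyperparameters, SamplerConfig, deconvolve,
                     evaluate_proportions)

spec = SyntheticSpec(G=200, C=3, N=20, seed=7)
rng = spec.rng()
S_true, W_true, X = simulate_truth(spec, rng)          # ground truth + bulk
S_ref = simulate_reference(S_true, spec, rng)          # noisy reference

result = deconvolve(
    X, S_ref, Hyperparameters(),
    SamplerConfig(n_chains=4, n_iterations=5000, seed=1),
)
report = evaluate_proportions(result.W_hat, W_true)
print(report.per_cell_type.round(4).to_string(index=False))
print(f"mean PCC {report.mean_pcc:.4f}  best chain {result.best_chain_index}")
```

Output:

```
cell_type  pcc    mae   rmse
      ct0  1.0 0.0010 0.0014
      ct1  1.0 0.0012 0.0015
      ct2  1.0 0.0009 0.0011
mean PCC 1.0000  best chain 0
```

Per cell type, `pcc` is the Pearson correlation between estimated and true
proportions across the 20 samples, and `mae`/`rmse` the corresponding
absolute errors on the proportion scale — here the estimates track the
truth essentially exactly despite the perturbed reference.
`result.S_hat` holds the inferred signatures, `result.sigma_c_hat` the
per-cell-type deviation scales, and `bedwars.cell_type_component` gives
each cell type's contribution Ŝ_c · Ŵ_c to the reconstructed bulk matrix.

The same pipeline is available from the shell:

```
bedwars fixtures --spec spec.yaml --out fix/
bedwars deconvolve --bulk fix/bulk.tsv --signature fix/ref.tsv \
    --chains 8 --iters 20000 --seed 1 --out out/
bedwars evaluate --est out/proportions.tsv --true fix/true_proportions.tsv \
    --out report.tsv
bedwars perturb --ref fix/ref.tsv --true fix/true_signature.tsv \
    --level 3 --bin-size 50 --seed 1 --out noisy/
bedwars simulate --sc fix/sc.tsv --labels fix/labels.tsv \
    --recipe pancreas --n 100 --cells 100 --seed 1 --out mixtures/
```

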