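"""Benchmarking machinery: signature construction from labeled single-cell
data, controlled two-stage perturbation of reference signatures, and
pseudo-bulk mixture generation with known ground truth.

The perturbation procedure emulates a reference signature that diverges from
the "true" signature underlying the bulk data by a controlled amount.  Per
cell type, genes are partitioned into equal-frequency bins by their
log-transformed true-signature value; within each bin the log reference
values are affinely rescaled around the bin mean so their standard deviation
becomes a target sigma (stage one, deterministic), then re-binned by
reference value into sub-bins of four genes whose values are shuffled (stage
two, stochastic).  Six noise levels NL-1..NL-6 use sigma = 1.0..2.25 in
steps of 0.25; each level yields 11 variants (the deterministic perturbation
plus ten independent shuffles).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .model import BulkMatrix, ProportionMatrix, SignatureMatrix

__all__ = [
    "LabeledSCMatrix",
    "NoiseConfig",
    "MixtureTruth",
    "NOISE_LEVEL_SIGMAS",
    "build_signature",
    "perturb_signature",
    "shuffle_variant",
    "make_noise_level_set",
    "generate_pseudobulk_pancreas",
    "generate_pseudobulk_brain",
]

logger = logging.getLogger("bedwars")

#: sigma used at noise level NL-k (1-based): 1.0, 1.25, ..., 2.25
NOISE_LEVEL_SIGMAS = {level: 1.0 + 0.25 * (level - 1) for level in range(1, 7)}


@dataclass
class LabeledSCMatrix:
    """Single-cell expression (genes x cells) with one cell-type label per cell."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    cell_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("shape inconsistent with gene/cell identifiers")
        if len(self.cell_labels) != len(self.cell_ids):
            raise ValueError("one label required per cell")
        if np.any(self.values < 0):
            raise ValueError("expression must be non-negative")

    @property
    def label_set(self) -> list[str]:
        return sorted(set(self.cell_labels))


@dataclass
class NoiseConfig:
    """Parameters of the two-stage signature perturbation.

    sigma : target within-bin standard deviation of log reference values.
    bin_size : genes per equal-frequency (true-signature) bin.
    shuffle_bin_size : genes per shuffled sub-bin (stage two).
    n_shuffled_variants : shuffled variants per noise level.
    exempt_cell_types : cell types passed through unperturbed.
    """

    sigma: float = 1.0
    bin_size: int = 100
    shuffle_bin_size: int = 4
    n_shuffled_variants: int = 10
    exempt_cell_types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.bin_size < self.shuffle_bin_size:
            raise ValueError("bin_size must be at least shuffle_bin_size")


@dataclass
class MixtureTruth:
    """Ground truth attached to a set of simulated pseudo-bulk mixtures."""

    proportions: ProportionMatrix
    selected_types: list[list[str]]
    true_signature: SignatureMatrix
    cells_used: list[list[str]]
    realized_counts: np.ndarray | None = None


def build_signature(
    sc: LabeledSCMatrix, min_expr_filter: float | None = 1.0
) -> SignatureMatrix:
    """Per-cell-type mean expression profiles.

    Column c is the mean over cells labeled c.  When ``min_expr_filter`` is
    set (default 1, i.e. one RPKM/FPKM), only genes whose mean exceeds the
    filter in at least one cell type are retained.
    """
    labels = sc.label_set
    arr = np.asarray(sc.cell_labels)
    cols = []
    for lab in labels:
        mask = arr == lab
        if not mask.any():
            raise ValueError(f"cell type {lab!r} has no cells")
        cols.append(sc.values[:, mask].mean(axis=1))
    V = np.column_stack(cols)
    genes = list(sc.gene_ids)
    if min_expr_filter is not None:
        keep = np.any(V > min_expr_filter, axis=1)
        logger.info(
            "signature filter > %g: keeping %d of %d genes",
            min_expr_filter,
            int(keep.sum()),
            len(keep),
        )
        V = V[keep]
        genes = [g for g, k in zip(genes, keep) if k]
    return SignatureMatrix(V, genes, labels)


def _equal_frequency_bins(
    true_log: np.ndarray, bin_size: int
) -> list[np.ndarray]:
    """Index groups of consecutive ``bin_size`` genes ordered by true value.

    The last bin absorbs any remainder (size bin_size..2*bin_size-1); ties in
    the true values are broken by the stable sort, i.e. original gene order.
    """
    order = np.argsort(true_log, kind="stable")
    n = len(order)
    n_bins = max(1, n // bin_size)
    bins = [order[i * bin_size : (i + 1) * bin_size] for i in range(n_bins - 1)]
    bins.append(order[(n_bins - 1) * bin_size :])
    return bins


def perturb_signature(
    ref_column: np.ndarray, true_column: np.ndarray, cfg: NoiseConfig
) -> np.ndarray:
    """Deterministic perturbation stage for one cell type.

    On the log scale, within each equal-frequency (true-signature) bin the
    reference values x are replaced by mean(x) + k*(x - mean(x)) with
    k = sigma / sd(x) (sample sd), so the bin mean is preserved exactly and
    the bin sd becomes sigma.  Returns linear-scale values.
    """
    ref_column = np.asarray(ref_column, dtype=float)
    true_column = np.asarray(true_column, dtype=float)
    if ref_column.shape != true_column.shape:
        raise ValueError("reference and true columns must have equal length")
    if np.any(ref_column <= 0) or np.any(true_column <= 0):
        raise ValueError(
            "perturbation requires strictly positive values; exclude "
            "zero-expression genes first"
        )
    log_ref = np.log(ref_column)
    log_true = np.log(true_column)
    out = log_ref.copy()
    for idx in _equal_frequency_bins(log_true, cfg.bin_size):
        x = log_ref[idx]
        m = x.mean()
        sd = x.std(ddof=1) if len(x) > 1 else 0.0
        if sd == 0.0:
            warnings.warn(
                "bin with zero variance: values collapse to the bin mean "
                "(target sd unreachable by scaling)",
                stacklevel=2,
            )
            k = 0.0
        else:
            k = cfg.sigma / sd
        out[idx] = m + k * (x - m)
    return np.exp(out)


def shuffle_variant(
    perturbed_column: np.ndarray,
    true_column: np.ndarray,
    cfg: NoiseConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stochastic stage: shuffle values within sub-bins of nearby genes.

    Within each equal-frequency (true-signature) bin, genes are ordered by
    their stage-one perturbed value and grouped into consecutive sub-bins of
    ``shuffle_bin_size``; values are permuted uniformly at random within each
    sub-bin, leaving every outer bin's value multiset unchanged.
    """
    perturbed_column = np.asarray(perturbed_column, dtype=float)
    true_column = np.asarray(true_column, dtype=float)
    out = perturbed_column.copy()
    log_true = np.log(true_column)
    for idx in _equal_frequency_bins(log_true, cfg.bin_size):
        vals = out[idx]
        inner = idx[np.argsort(vals, kind="stable")]
        for start in range(0, len(inner), cfg.shuffle_bin_size):
            sub = inner[start : start + cfg.shuffle_bin_size]
            out[sub] = out[sub][rng.permutation(len(sub))]
    return out


def make_noise_level_set(
    S_ref: SignatureMatrix,
    S_true: SignatureMatrix,
    level: int,
    cfg: NoiseConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[SignatureMatrix]:
    """All 11 reference variants at one noise level (NL-1..NL-6).

    Variant 0 is the deterministic perturbation at sigma = 1 + 0.25*(level-1);
    the remaining ``cfg.n_shuffled_variants`` are independent shuffles of it.
    Cell types listed in ``cfg.exempt_cell_types`` pass through unperturbed.
    """
    if level not in NOISE_LEVEL_SIGMAS:
        raise ValueError("noise level must be in 1..6")
    if S_ref.gene_ids != S_true.gene_ids or S_ref.cell_types != S_true.cell_types:
        raise ValueError("reference and true signatures must be aligned")
    cfg = replace(cfg or NoiseConfig(), sigma=NOISE_LEVEL_SIGMAS[level])
    rng = rng if rng is not None else np.random.default_rng(0)
    exempt = set(cfg.exempt_cell_types)
    det = np.empty_like(S_ref.values)
    for j, ct in enumerate(S_ref.cell_types):
        if ct in exempt:
            det[:, j] = S_ref.values[:, j]
        else:
            det[:, j] = perturb_signature(
                S_ref.values[:, j], S_true.values[:, j], cfg
            )
    variants = [SignatureMatrix(det.copy(), list(S_ref.gene_ids), list(S_ref.cell_types))]
    for _ in range(cfg.n_shuffled_variants):
        shuf = np.empty_like(det)
        for j, ct in enumerate(S_ref.cell_types):
            if ct in exempt:
                shuf[:, j] = det[:, j]
            else:
                shuf[:, j] = shuffle_variant(
                    det[:, j], S_true.values[:, j], cfg, rng
                )
        variants.append(
            SignatureMatrix(shuf, list(S_ref.gene_ids), list(S_ref.cell_types))
        )
    return variants


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights`` (sum exact)."""
    quota = weights * total
    counts = np.floor(quota).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(quota - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def _cells_by_type(sc: LabeledSCMatrix) -> dict[str, np.ndarray]:
    arr = np.asarray(sc.cell_labels)
    return {lab: np.flatnonzero(arr == lab) for lab in sc.label_set}


def generate_pseudobulk_pancreas(
    sc: LabeledSCMatrix,
    n_mixtures: int = 100,
    cells_per_mixture: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[BulkMatrix, MixtureTruth]:
    """Pseudo-bulk mixtures with controlled cell-type composition.

    Per mixture: the number of present cell types k is uniform on {2..K};
    k types are drawn without replacement; their weights are uniform on
    [0.05, 1] normalized to sum one; ``cells_per_mixture`` cells are sampled
    (without replacement within a type) at those proportions and averaged.
    Recorded "true" proportions are the continuous normalized weights;
    realized cell counts are stored alongside.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    types = sc.label_set
    K = len(types)
    if K < 2:
        raise ValueError("pancreas-style mixtures require at least two cell types")
    by_type = _cells_by_type(sc)
    G = sc.values.shape[0]
    X = np.empty((G, n_mixtures))
    props = np.zeros((K, n_mixtures))
    counts_all = np.zeros((K, n_mixtures), dtype=int)
    selected: list[list[str]] = []
    cells_used: list[list[str]] = []
    for i in range(n_mixtures):
        k = int(rng.integers(2, K + 1))
        chosen = rng.choice(K, size=k, replace=False)
        raw = rng.uniform(0.05, 1.0, size=k)
        w = raw / raw.sum()
        counts = _largest_remainder(w, cells_per_mixture)
        cols: list[int] = []
        for t, c in zip(chosen, counts):
            pool = by_type[types[t]]
            if c > len(pool):
                raise ValueError(
                    f"cell type {types[t]!r} has only {len(pool)} cells but "
                    f"{c} were requested"
                )
            cols.extend(rng.choice(pool, size=c, replace=False).tolist())
        X[:, i] = sc.values[:, cols].mean(axis=1)
        props[chosen, i] = w
        counts_all[chosen, i] = counts
        selected.append([types[t] for t in chosen])
        cells_used.append([sc.cell_ids[c] for c in cols])
    truth = MixtureTruth(
        proportions=ProportionMatrix(
            props, types, [f"mix{i}" for i in range(n_mixtures)]
        ),
        selected_types=selected,
        true_signature=build_signature(sc, min_expr_filter=None),
        cells_used=cells_used,
        realized_counts=counts_all,
    )
    bulk = BulkMatrix(X, list(sc.gene_ids), [f"mix{i}" for i in range(n_mixtures)])
    return bulk, truth


def generate_pseudobulk_brain(
    sc: LabeledSCMatrix,
    n_mixtures: int = 100,
    cells_per_mixture: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[BulkMatrix, MixtureTruth]:
    """Pseudo-bulk mixtures by unconstrained cell sampling.

    Per mixture, ``cells_per_mixture`` cells are drawn uniformly without
    replacement from the whole dataset and averaged; true proportions are the
    realized label fractions among the sampled cells.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    n_cells = len(sc.cell_ids)
    if cells_per_mixture > n_cells:
        raise ValueError(
            f"cells_per_mixture={cells_per_mixture} exceeds the {n_cells} "
            "available cells"
        )
    types = sc.label_set
    type_index = {t: i for i, t in enumerate(types)}
    G = sc.values.shape[0]
    X = np.empty((G, n_mixtures))
    props = np.zeros((len(types), n_mixtures))
    selected: list[list[str]] = []
    cells_used: list[list[str]] = []
    labels = np.asarray(sc.cell_labels)
    for i in range(n_mixtures):
        cols = rng.choice(n_cells, size=cells_per_mixture, replace=False)
        X[:, i] = sc.values[:, cols].mean(axis=1)
        for lab in labels[cols]:
            props[type_index[lab], i] += 1
        props[:, i] /= cells_per_mixture
        # compensate the largest entry so label fractions sum to 1 exactly
        props[np.argmax(props[:, i]), i] += 1.0 - props[:, i].sum()
        selected.append(sorted(set(labels[cols])))
        cells_used.append([sc.cell_ids[c] for c in cols])
    truth = MixtureTruth(
        proportions=ProportionMatrix(
            props, types, [f"mix{i}" for i in range(n_mixtures)]
        ),
        selected_types=selected,
        true_signature=build_signature(sc, min_expr_filter=None),
        cells_used=cells_used,
    )
    bulk = BulkMatrix(X, list(sc.gene_ids), [f"mix{i}" for i in range(n_mixtures)])
    return bulk, truth
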