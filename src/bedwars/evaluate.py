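"""Per-cell-type evaluation of estimated proportions and signatures, and a
non-negative least-squares comparator.

Proportions are compared per cell type across samples; signatures per cell
type across genes (on natural-log values by default).  Metrics: Pearson
correlation (PCC), mean absolute error (MAE) and root mean squared error
(RMSE), each also averaged over cell types.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .model import BulkMatrix, ProportionMatrix, SignatureMatrix

__all__ = [
    "EvaluationReport",
    "evaluate_proportions",
    "evaluate_signatures",
    "nnls_baseline",
]

logger = logging.getLogger("bedwars")


@dataclass
class EvaluationReport:
    """Per-cell-type metric table plus cell-type averages."""

    per_cell_type: pd.DataFrame  # columns: cell_type, pcc, mae, rmse
    n_samples: int
    target: str  # "proportions" | "signatures"

    @property
    def mean_pcc(self) -> float:
        return float(self.per_cell_type["pcc"].mean(skipna=True))

    @property
    def mean_mae(self) -> float:
        return float(self.per_cell_type["mae"].mean())

    @property
    def mean_rmse(self) -> float:
        return float(self.per_cell_type["rmse"].mean())


def _pcc(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _metric_rows(
    est: np.ndarray, true: np.ndarray, labels: list[str]
) -> pd.DataFrame:
    rows = []
    for i, lab in enumerate(labels):
        e, t = est[i], true[i]
        pcc = _pcc(e, t)
        if np.isnan(pcc):
            logger.info(
                "cell type %s: zero variance, PCC undefined (excluded from "
                "the PCC average)",
                lab,
            )
        diff = e - t
        rows.append(
            {
                "cell_type": lab,
                "pcc": pcc,
                "mae": float(np.mean(np.abs(diff))),
                "rmse": float(np.sqrt(np.mean(diff**2))),
            }
        )
    return pd.DataFrame(rows)


def _align(
    est_labels: list[str], true_labels: list[str], allow_subset: bool
) -> list[str]:
    if set(est_labels) == set(true_labels):
        return list(true_labels)
    if not allow_subset:
        raise ValueError(
            "estimated and true cell types differ "
            f"(only-estimated: {sorted(set(est_labels) - set(true_labels))}, "
            f"only-true: {sorted(set(true_labels) - set(est_labels))}); "
            "pass allow_subset=True to evaluate the intersection"
        )
    common = [t for t in true_labels if t in set(est_labels)]
    logger.info("evaluating %d shared cell types", len(common))
    if not common:
        raise ValueError("no shared cell types")
    return common


def evaluate_proportions(
    W_hat: ProportionMatrix,
    W_true: ProportionMatrix,
    allow_subset: bool = False,
) -> EvaluationReport:
    """Compare estimated and true proportions per cell type across samples.

    Rows are aligned by cell-type label and columns by sample identifier,
    never by position.
    """
    if set(W_hat.sample_ids) != set(W_true.sample_ids):
        raise ValueError("estimated and true sample sets differ")
    cts = _align(W_hat.cell_types, W_true.cell_types, allow_subset)
    order = [W_hat.sample_ids.index(s) for s in W_true.sample_ids]
    est = np.array([W_hat.row(ct)[order] for ct in cts])
    true = np.array([W_true.row(ct) for ct in cts])
    return EvaluationReport(
        per_cell_type=_metric_rows(est, true, cts),
        n_samples=W_true.n_samples,
        target="proportions",
    )


def evaluate_signatures(
    S_hat: SignatureMatrix,
    S_true: SignatureMatrix,
    log_scale: bool = True,
    allow_subset: bool = False,
) -> EvaluationReport:
    """Compare estimated and true signatures per cell type across genes.

    Computed on natural-log values by default; genes outside the shared set
    (or non-positive under log scaling) are dropped with a logged count.
    """
    cts = _align(S_hat.cell_types, S_true.cell_types, allow_subset)
    true_index = {g: i for i, g in enumerate(S_true.gene_ids)}
    shared = [g for g in S_hat.gene_ids if g in true_index]
    hi = {g: i for i, g in enumerate(S_hat.gene_ids)}
    est = np.array(
        [[S_hat.values[hi[g], S_hat.cell_types.index(ct)] for g in shared] for ct in cts]
    )
    true = np.array(
        [
            [S_true.values[true_index[g], S_true.cell_types.index(ct)] for g in shared]
            for ct in cts
        ]
    )
    if log_scale:
        pos = np.all(est > 0, axis=0) & np.all(true > 0, axis=0)
        if not np.all(pos):
            logger.info("dropping %d non-positive genes for log-scale metrics",
                        int((~pos).sum()))
        est, true = np.log(est[:, pos]), np.log(true[:, pos])
    n_genes = est.shape[1]
    logger.info("signature evaluation on %d shared genes", n_genes)
    if n_genes < 3:
        raise ValueError("fewer than 3 shared genes; cannot evaluate signatures")
    return EvaluationReport(
        per_cell_type=_metric_rows(est, true, cts),
        n_samples=n_genes,
        target="signatures",
    )


def nnls_baseline(X: BulkMatrix, S_ref: SignatureMatrix) -> ProportionMatrix:
    """Non-negative least-squares proportion estimates, per sample,
    renormalized to the simplex.  A deterministic comparator."""
    if X.gene_ids != S_ref.gene_ids:
        raise ValueError("bulk and signature gene orderings differ")
    C, N = S_ref.n_cell_types, X.n_samples
    W = np.empty((C, N))
    for n in range(N):
        coef, _ = nnls(S_ref.values, X.values[:, n])
        total = coef.sum()
        if total == 0:
            warnings.warn(
                f"all-zero NNLS fit for sample {X.sample_ids[n]}; "
                "reporting uniform proportions",
                stacklevel=2,
            )
            coef = np.full(C, 1.0 / C)
            total = 1.0
        W[:, n] = coef / total
    return ProportionMatrix(W, list(S_ref.cell_types), list(X.sample_ids))
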