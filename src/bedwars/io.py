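"""Readers and writers for expression matrices, plus gene harmonization and
simple single-cell QC filters shared by all commands.

Dense matrices are tab- or comma-separated text with a header row of sample
or cell-type identifiers and the gene identifier in the first column.
Single-cell inputs may instead be a matrix-market (MTX) triplet accompanied
by gene-id and cell-id sidecar files (one identifier per line) and a
two-column (cell_id, label) TSV of cell-type labels.  All matrices are held
genes-as-rows internally; readers accept either orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .benchmark import LabeledSCMatrix
from .model import BulkMatrix, ProportionMatrix, SignatureMatrix

__all__ = [
    "MatrixFile",
    "read_matrix",
    "read_table",
    "write_matrix",
    "read_labels",
    "write_labels",
    "harmonize",
    "qc_filter_cells",
]

logger = logging.getLogger("bedwars")


@dataclass
class MatrixFile:
    """Description of an on-disk expression matrix.

    ``format`` is "tsv", "csv" or "mtx"; for "mtx" the ``row_ids`` and
    ``col_ids`` sidecar paths are required.  ``genes_as_rows`` declares the
    orientation of the stored table (the in-memory result is always
    genes x columns).
    """

    path: str | Path
    format: str | None = None
    genes_as_rows: bool = True
    delimiter: str | None = None
    row_ids: str | Path | None = None
    col_ids: str | Path | None = None

    def resolved_format(self) -> str:
        if self.format:
            return self.format
        suffix = Path(self.path).suffix.lower()
        return {".csv": "csv", ".mtx": "mtx"}.get(suffix, "tsv")


def _collapse_duplicate_genes(df: pd.DataFrame, strict: bool) -> pd.DataFrame:
    dup = df.index.duplicated()
    if dup.any():
        if strict:
            raise ValueError(f"{int(dup.sum())} duplicate gene identifiers")
        logger.warning("summing %d duplicate gene identifiers", int(dup.sum()))
        df = df.groupby(level=0, sort=False).sum()
    return df


def read_table(
    file: MatrixFile | str | Path, strict_duplicates: bool = False
) -> pd.DataFrame:
    """Load an expression table as a genes x columns DataFrame."""
    if not isinstance(file, MatrixFile):
        file = MatrixFile(path=file)
    fmt = file.resolved_format()
    path = Path(file.path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "mtx":
        if file.row_ids is None or file.col_ids is None:
            raise ValueError("mtx input requires row_ids and col_ids sidecar files")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        rows = Path(file.row_ids).read_text().split()
        cols = Path(file.col_ids).read_text().split()
        if mat.shape != (len(rows), len(cols)):
            raise ValueError(
                f"mtx shape {mat.shape} does not match sidecar identifier "
                f"counts ({len(rows)}, {len(cols)})"
            )
        df = pd.DataFrame(np.asarray(mat, dtype=float), index=rows, columns=cols)
    else:
        sep = file.delimiter or ("," if fmt == "csv" else "\t")
        try:
            df = pd.read_csv(path, sep=sep, index_col=0,
                             float_precision="round_trip")
        except (pd.errors.ParserError, ValueError) as exc:
            raise ValueError(f"cannot parse {path}: {exc}") from exc
        non_numeric = df.columns[
            ~df.dtypes.map(lambda t: np.issubdtype(t, np.number))
        ]
        if len(non_numeric):
            raise ValueError(
                f"non-numeric values in column(s) {list(non_numeric)} of {path}"
            )
        df = df.astype(float)
    if not file.genes_as_rows:
        df = df.T
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate column identifiers in {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df = _collapse_duplicate_genes(df, strict_duplicates)
    logger.info("read %s: %d genes x %d columns", path, *df.shape)
    return df


def read_matrix(
    file: MatrixFile | str | Path,
    kind: str = "bulk",
    labels: str | Path | pd.Series | None = None,
    strict_duplicates: bool = False,
) -> BulkMatrix | SignatureMatrix | LabeledSCMatrix:
    """Read an expression matrix as a typed container.

    ``kind`` selects the container: "bulk" (genes x samples), "signature"
    (genes x cell types), "proportions" (cell types x samples; the stored
    table's rows are cell types) or "sc" (genes x cells; requires ``labels``).
    """
    if kind == "proportions":
        df = read_table(
            file if isinstance(file, MatrixFile) else MatrixFile(path=file),
            strict_duplicates=True,
        )
        return ProportionMatrix(df.to_numpy(), list(df.index), list(df.columns))
    df = read_table(file, strict_duplicates=strict_duplicates)
    if kind == "bulk":
        return BulkMatrix(df.to_numpy(), list(df.index), list(df.columns))
    if kind == "signature":
        return SignatureMatrix(df.to_numpy(), list(df.index), list(df.columns))
    if kind == "sc":
        if labels is None:
            raise ValueError("single-cell input requires cell-type labels")
        lab = labels if isinstance(labels, pd.Series) else read_labels(labels)
        missing = [c for c in df.columns if c not in lab.index]
        if missing:
            raise ValueError(f"{len(missing)} cells lack labels, e.g. {missing[:3]}")
        return LabeledSCMatrix(
            values=df.to_numpy(),
            gene_ids=list(df.index),
            cell_ids=list(df.columns),
            cell_labels=[str(lab[c]) for c in df.columns],
        )
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(
    obj: BulkMatrix | SignatureMatrix | ProportionMatrix | LabeledSCMatrix,
    path: str | Path,
) -> None:
    """Write a typed matrix as dense TSV (full float precision round-trip)."""
    if isinstance(obj, BulkMatrix):
        df = pd.DataFrame(obj.values, index=obj.gene_ids, columns=obj.sample_ids)
        df.index.name = "gene"
    elif isinstance(obj, SignatureMatrix):
        df = pd.DataFrame(obj.values, index=obj.gene_ids, columns=obj.cell_types)
        df.index.name = "gene"
    elif isinstance(obj, ProportionMatrix):
        df = pd.DataFrame(obj.values, index=obj.cell_types, columns=obj.sample_ids)
        df.index.name = "cell_type"
    elif isinstance(obj, LabeledSCMatrix):
        df = pd.DataFrame(obj.values, index=obj.gene_ids, columns=obj.cell_ids)
        df.index.name = "gene"
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column (cell_id, label) TSV into a Series indexed by cell."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"label file {path} must have exactly two columns")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def write_labels(sc: LabeledSCMatrix, path: str | Path) -> None:
    pd.DataFrame({"cell_id": sc.cell_ids, "label": sc.cell_labels}).to_csv(
        path, sep="\t", index=False
    )


def harmonize(
    X: BulkMatrix, S_ref: SignatureMatrix, strict: bool = False
) -> tuple[BulkMatrix, SignatureMatrix]:
    """Restrict bulk and reference to a shared, model-ready gene set.

    Genes are intersected (reference order kept), then genes with a zero in
    any reference column are dropped so the log-scale signature prior is
    defined; with ``strict`` genes with a zero in any bulk sample are dropped
    too.  Counts are logged at each step.
    """
    bulk_index = {g: i for i, g in enumerate(X.gene_ids)}
    common = [g for g in S_ref.gene_ids if g in bulk_index]
    if not common:
        raise ValueError("bulk and reference matrices share no genes")
    n_dropped = len(set(X.gene_ids) | set(S_ref.gene_ids)) - len(common)
    logger.info("gene intersection: %d shared, %d dropped", len(common), n_dropped)
    ref_index = {g: i for i, g in enumerate(S_ref.gene_ids)}
    xi = np.array([bulk_index[g] for g in common])
    si = np.array([ref_index[g] for g in common])
    Xv = X.values[xi]
    Sv = S_ref.values[si]
    keep = np.all(Sv > 0, axis=1)
    if strict:
        keep &= np.all(Xv > 0, axis=1)
    n_zero = int((~keep).sum())
    if n_zero:
        logger.info("dropping %d genes with zero expression", n_zero)
    if not keep.any():
        raise ValueError("no genes remain after zero-expression filtering")
    genes = [g for g, k in zip(common, keep) if k]
    return (
        BulkMatrix(Xv[keep], genes, list(X.sample_ids)),
        SignatureMatrix(Sv[keep], genes, list(S_ref.cell_types)),
    )


def _mad_outliers(stat: np.ndarray, threshold: float) -> np.ndarray:
    med = np.median(stat)
    mad = np.median(np.abs(stat - med))  # plain MAD, no consistency constant
    if mad == 0:
        return stat != med
    return np.abs(stat - med) > threshold * mad


def qc_filter_cells(
    sc: LabeledSCMatrix,
    mad_threshold: float = 3.0,
    min_nonzero_frac: float = 0.05,
    ribosomal_genes: list[str] | None = None,
    mitochondrial_genes: list[str] | None = None,
) -> LabeledSCMatrix:
    """Median-absolute-deviation cell filter plus a gene detection filter.

    Cells whose library size (and, when the gene lists are supplied,
    ribosomal or mitochondrial content fraction) lies more than
    ``mad_threshold`` MADs from the median are removed; genes with nonzero
    values in fewer than ``min_nonzero_frac`` of the remaining cells are
    removed.
    """
    V = sc.values
    lib = V.sum(axis=0)
    bad = _mad_outliers(lib, mad_threshold)
    for name, genes in (
        ("ribosomal", ribosomal_genes),
        ("mitochondrial", mitochondrial_genes),
    ):
        if genes is None:
            logger.info("no %s gene list supplied; skipping that filter", name)
            continue
        rows = [i for i, g in enumerate(sc.gene_ids) if g in set(genes)]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = V[rows].sum(axis=0) / np.where(lib > 0, lib, np.nan)
        frac = np.nan_to_num(frac)
        bad |= _mad_outliers(frac, mad_threshold)
    keep_cells = ~bad
    logger.info("QC: removing %d of %d cells", int(bad.sum()), len(bad))
    if not keep_cells.any():
        raise ValueError("QC removed every cell")
    V = V[:, keep_cells]
    nonzero_frac = (V > 0).mean(axis=1)
    keep_genes = nonzero_frac >= min_nonzero_frac
    logger.info(
        "QC: keeping %d of %d genes (nonzero in >= %.0f%% of cells)",
        int(keep_genes.sum()),
        len(keep_genes),
        100 * min_nonzero_frac,
    )
    return LabeledSCMatrix(
        values=V[keep_genes],
        gene_ids=[g for g, k in zip(sc.gene_ids, keep_genes) if k],
        cell_ids=[c for c, k in zip(sc.cell_ids, keep_cells) if k],
        cell_labels=[l for l, k in zip(sc.cell_labels, keep_cells) if k],
    )
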