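"""Domain types and I/O for expression matrices, gene annotation and region tables.

Expression is held as an ``n x p`` matrix (patients in rows, genes in
columns) with genes ordered along the genome: by chromosome, then start
coordinate.  All downstream modelling assumes *standardized* columns under
the ``1/n`` convention, i.e. each gene has mean 0 and ``sum(y**2)/n == 1``,
so that the empirical Gram matrix ``G_hat = Y.T @ Y / n`` has unit diagonal
and its off-diagonal entries are the empirical correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneAnnotation",
    "read_annotation",
    "read_expression",
    "write_expression",
    "log_transform",
    "standardize",
    "drop_degenerate_genes",
    "write_region_table",
    "read_region_table",
    "region_table_to_bed",
]

REGION_TABLE_COLUMNS = [
    "chromosome",
    "first_gene_index",
    "last_gene_index",
    "first_gene_id",
    "last_gene_id",
    "p_k",
    "rho_k",
    "T_k",
    "pvalue",
    "adjusted_pvalue",
    "significant",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene coordinates in BED convention (0-based, half-open intervals).

    The frame has columns ``gene_id, chromosome, start, end[, strand]`` and is
    sorted by chromosome then start, ties broken by gene id.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if (t["start"] >= t["end"]).any():
            bad = t.loc[t["start"] >= t["end"], "gene_id"].iloc[0]
            raise ValueError(f"annotation interval with start >= end for gene {bad!r}")
        if t["gene_id"].duplicated().any():
            dup = t.loc[t["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicated gene id in annotation: {dup!r}")

    @property
    def gene_ids(self) -> np.ndarray:
        return self.table["gene_id"].to_numpy()

    def sorted(self) -> "GeneAnnotation":
        t = self.table.sort_values(
            ["chromosome", "start", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)
        return GeneAnnotation(t)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Expression values for ``n`` patients over ``p`` genome-ordered genes.

    ``values`` is ``n x p``; ``gene_order_index`` is the 1-based position of
    each gene within its chromosome.  ``standardized`` records whether the
    columns have been centred and scaled under the 1/n convention.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    chromosome: np.ndarray
    sample_ids: np.ndarray
    start: np.ndarray | None = None
    end: np.ndarray | None = None
    standardized: bool = False
    gene_order_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D patients x genes matrix")
        if self.values.shape[1] != len(self.gene_ids):
            raise ValueError("gene_ids length does not match number of columns")
        if self.gene_order_index is None:
            idx = np.empty(self.p, dtype=int)
            for chrom in pd.unique(self.chromosome):
                mask = self.chromosome == chrom
                idx[mask] = np.arange(1, mask.sum() + 1)
            object.__setattr__(self, "gene_order_index", idx)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def chromosomes(self) -> list:
        """Chromosome labels in genome order (first appearance)."""
        return list(pd.unique(self.chromosome))

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        return replace(
            self,
            values=self.values[:, mask],
            gene_ids=self.gene_ids[mask],
            chromosome=self.chromosome[mask],
            start=None if self.start is None else self.start[mask],
            end=None if self.end is None else self.end[mask],
            gene_order_index=None,
        )

    def chromosome_view(self, chrom) -> "ExpressionMatrix":
        return self.subset_genes(self.chromosome == chrom)


def read_annotation(path) -> GeneAnnotation:
    """Read a BED file (chrom, start, end, name[, score, strand])."""
    t = pd.read_csv(path, sep="\t", header=None, comment="#")
    if t.shape[1] < 4:
        raise ValueError("annotation BED needs at least 4 columns (chrom, start, end, name)")
    out = pd.DataFrame(
        {
            "gene_id": t.iloc[:, 3].astype(str),
            "chromosome": t.iloc[:, 0].astype(str),
            "start": t.iloc[:, 1].astype(int),
            "end": t.iloc[:, 2].astype(int),
        }
    )
    if t.shape[1] >= 6:
        out["strand"] = t.iloc[:, 5].astype(str)
    return GeneAnnotation(out).sorted()


def read_expression(path, annotation: GeneAnnotation) -> ExpressionMatrix:
    """Read a TSV expression table (rows = genes, first column gene id).

    Genes are reordered along the genome following ``annotation``; genes
    absent from the annotation are dropped with a warning.  The returned
    matrix is raw (unstandardized).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicated gene id in expression file: {dup!r}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().to_numpy().any() and not df[col].isna().to_numpy().any():
            row = df.index[coerced.isna().to_numpy().argmax()]
            raise ValueError(f"non-numeric expression value at gene {row!r}, sample {col!r}")
        df[col] = coerced
    if df.isna().to_numpy().any():
        raise ValueError("missing expression values are not supported")

    ann = annotation.sorted().table
    known = set(df.index.astype(str))
    keep = ann[ann["gene_id"].isin(known)]
    missing = known - set(ann["gene_id"])
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) absent from annotation dropped: "
            f"{sorted(missing)[:5]}{'...' if len(missing) > 5 else ''}"
        )
    if keep.empty:
        raise ValueError("no expression gene id found in the annotation")
    ordered = df.loc[keep["gene_id"].to_numpy()]
    return ExpressionMatrix(
        values=np.ascontiguousarray(ordered.to_numpy(dtype=float).T),
        gene_ids=keep["gene_id"].to_numpy(),
        chromosome=keep["chromosome"].to_numpy(),
        sample_ids=np.asarray(df.columns, dtype=object),
        start=keep["start"].to_numpy(),
        end=keep["end"].to_numpy(),
    )


def write_expression(expr: ExpressionMatrix, path, float_format: str = "%.17g") -> None:
    """Write genes x samples TSV, inverse of :func:`read_expression`."""
    df = pd.DataFrame(expr.values.T, index=expr.gene_ids, columns=expr.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format=float_format)


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Apply ``log(1 + x)`` to every value (RNA-seq count stabilisation)."""
    if (expr.values < 0).any():
        raise ValueError("log_transform requires non-negative values")
    return replace(expr, values=np.log1p(expr.values), standardized=False)


def drop_degenerate_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes that are constant (including all-zero) across patients."""
    variances = expr.values.var(axis=0)
    degenerate = variances == 0
    if degenerate.any():
        names = expr.gene_ids[degenerate]
        warnings.warn(
            f"removed {degenerate.sum()} gene(s) with no variation: "
            f"{list(names[:5])}{'...' if degenerate.sum() > 5 else ''}"
        )
    out = expr.subset_genes(~degenerate)
    if out.p == 0:
        warnings.warn("no genes left after removing degenerate ones")
    return out


def standardize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Centre and scale each gene column with the 1/n variance convention.

    After this step ``Y.T @ Y / n`` has exact unit diagonal, which the
    segmentation likelihood (and the identity ``T = n * lambda(p, rho_hat)``)
    relies on.
    """
    y = expr.values
    mean = y.mean(axis=0)
    sd = y.std(axis=0)  # ddof=0: the 1/n convention
    if (sd == 0).any():
        gene = expr.gene_ids[(sd == 0).argmax()]
        raise ValueError(
            f"gene {gene!r} has zero variance; drop degenerate genes before standardize"
        )
    return replace(expr, values=(y - mean) / sd, standardized=True)


def write_region_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_region_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def region_table_to_bed(table: pd.DataFrame, expr: ExpressionMatrix, path) -> None:
    """Export regions as BED using first-gene start to last-gene end."""
    if expr.start is None or expr.end is None:
        raise ValueError("expression matrix carries no genomic coordinates")
    pos = {(c, i): k for k, (c, i) in enumerate(zip(expr.chromosome, expr.gene_order_index))}
    rows = []
    for _, r in table.iterrows():
        a = pos[(r["chromosome"], r["first_gene_index"])]
        b = pos[(r["chromosome"], r["last_gene_index"])]
        rows.append((r["chromosome"], expr.start[a], expr.end[b],
                     f"region_{r['first_gene_id']}_{r['last_gene_id']}"))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
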