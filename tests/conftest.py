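import numpy as np
import pandas as pd
import pytest

from segcorr.io import ExpressionMatrix, GeneAnnotation, standardize


@pytest.fixture
def rng():
    return np.random.default_rng(20250101)


def make_expression(values, chrom=None, standardized=False, sample_prefix="s", gene_ids=None):
    """Build an ExpressionMatrix around a raw n x p array."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if chrom is None:
        chrom = ["chr1"] * p
    if gene_ids is None:
        gene_ids = [f"g{j+1}" for j in range(p)]
    return ExpressionMatrix(
        values=values,
        gene_ids=np.asarray(gene_ids, dtype=object),
        chromosome=np.asarray(chrom, dtype=object),
        sample_ids=np.array([f"{sample_prefix}{i+1}" for i in range(n)], dtype=object),
        start=np.arange(p) * 1000,
        end=np.arange(p) * 1000 + 500,
        standardized=standardized,
    )


def standardized_block(rng, n, p):
    """Random standardized block (1/n convention)."""
    y = rng.standard_normal((n, p))
    return standardize(make_expression(y)).values


@pytest.fixture
def toy_annotation():
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["gA", "gB", "gC"],
                "chromosome": ["chr1", "chr1", "chr1"],
                "start": [100, 300, 500],
                "end": [200, 400, 600],
            }
        )
    )


def write_expression_tsv(path, gene_ids, sample_ids, values):
    df = pd.DataFrame(np.asarray(values).T, index=gene_ids, columns=sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def write_bed(path, gene_ids, chroms, starts, ends):
    pd.DataFrame({0: chroms, 1: starts, 2: ends, 3: gene_ids}).to_csv(
        path, sep="\t", header=False, index=False
    )
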