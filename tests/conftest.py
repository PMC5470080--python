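import numpy as np
import pandas as pd
import pytest

from bsrseq.expression_deg import ExpressionMatrix
from bsrseq.formats_io import AlleleCountTable, GeneModel


@pytest.fixture
def small_table() -> AlleleCountTable:
    """Four sites exercising each filter outcome once (pooled counts match
    the canonical worked examples)."""
    rows = []

    def site(chrom, pos, counts):
        # split the pooled counts across two bulk cells of one condition
        half = {b: n // 2 for b, n in counts.items()}
        rest = {b: n - half[b] for b, n in counts.items()}
        for bulk, part in (("tolerant", half), ("sensitive", rest)):
            rows.append(
                {"chrom": chrom, "pos": pos, "bulk": bulk, "condition": "normal",
                 "A": part.get("A", 0), "C": part.get("C", 0),
                 "G": part.get("G", 0), "T": part.get("T", 0)}
            )

    site("chr1", 100, {"A": 10, "G": 10})          # pass
    site("chr1", 200, {"A": 12, "G": 2})           # low_type_support
    site("chr1", 300, {"A": 100, "G": 20, "T": 1})  # monomorphic (G < 20%)
    site("chr1", 400, {"A": 8, "G": 5, "T": 4})    # too_many_types
    return AlleleCountTable(pd.DataFrame(rows))


@pytest.fixture
def gene_models() -> list[GeneModel]:
    return [
        GeneModel("geneA", "chr1", 1000, 2000, "+"),
        GeneModel("geneB", "chr1", 1500, 2500, "-"),
        GeneModel("geneC", "chr2", 100, 900, "+"),
    ]


@pytest.fixture
def tiny_expression() -> ExpressionMatrix:
    counts = pd.DataFrame(
        {
            "s1": [1000, 0, 30],
            "s2": [980, 0, 25],
            "t1": [1000, 0, 300],
            "t2": [1020, 0, 310],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    lengths = pd.Series([2000, 1500, 1000], index=counts.index)
    lib = pd.Series([10_000_000] * 4, index=counts.columns)
    return ExpressionMatrix(counts=counts, lengths=lengths, library_sizes=lib)
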