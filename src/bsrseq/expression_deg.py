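"""Digital differential-expression calling on tag counts.

Expression is normalised as RPKM (reads per kilobase of exon model per
million mapped reads).  Differential expression between two sample groups is
tested on replicate-pooled tag counts with the Audic-Claverie digital test:
given ``x`` tags in a library of ``N1`` reads, the predictive distribution of
the count ``y'`` in a second library of ``N2`` reads is

    p(y' | x) = (N2/N1)^y' * (x + y')! / (x! * y'! * (1 + N2/N1)^(x + y' + 1))

which is the negative-binomial distribution with ``x + 1`` successes and
success probability ``N1 / (N1 + N2)``; the two-sided p-value is
``2 * min(P(Y <= y), P(Y >= y))`` capped at 1.  Benjamini-Hochberg step-up
adjustment controls the FDR, and a gene is a significant DEG when its
(pseudocounted mean-RPKM) fold change strictly exceeds the fold threshold
and its q-value is at or below the FDR threshold.  Significant calls are
binned by fold-change magnitude into (2, 10], (10, 100], (100, 1000] and
(1000, inf) for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import nbinom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ConsistencyError, DomainError

BIN_EDGES = (2.0, 10.0, 100.0, 1000.0)
BIN_LABELS = ("2-10", "10-100", "100-1000", ">1000")


@dataclass
class DegConfig:
    """Thresholds of the DEG call."""

    fold_change_threshold: float = 2.0
    fdr_threshold: float = 0.001
    pseudocount_rpkm: float = 0.01
    replicate_handling: str = "pool_sum"

    def __post_init__(self):
        if self.fold_change_threshold <= 1:
            raise ConfigError("fold_change_threshold must be > 1")
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ConfigError("fdr_threshold must lie in (0, 1)")
        if self.pseudocount_rpkm < 0:
            raise ConfigError("pseudocount_rpkm must be >= 0")
        if self.replicate_handling != "pool_sum":
            raise ConfigError("only pool_sum replicate handling is supported")


@dataclass
class ExpressionMatrix:
    """Gene x sample read counts with gene lengths and library sizes.

    Library sizes default to column sums when not supplied explicitly.
    """

    counts: pd.DataFrame
    lengths: pd.Series | None = None
    library_sizes: pd.Series | None = None

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ConfigError("counts must be non-negative")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(np.int64)
        else:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns)
            if self.library_sizes.isna().any():
                raise ConfigError("library sizes missing for some samples")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any():
                raise ConfigError("gene lengths missing for some genes")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def to_tsv(self, path) -> None:
        frame = self.counts.copy()
        if self.lengths is not None:
            frame.insert(0, "length", self.lengths)
        frame.to_csv(path, sep="\t", index_label="gene_id")


def compute_rpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """RPKM(g, s) = 1e9 * C(g, s) / (N(s) * L(g))."""
    if matrix.lengths is None:
        raise DomainError("RPKM requires gene lengths")
    lengths = matrix.lengths.to_numpy(dtype=float)
    lib = matrix.library_sizes.to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise DomainError("gene lengths must be > 0")
    if (lib <= 0).any():
        raise DomainError("library sizes must be > 0")
    vals = 1e9 * matrix.counts.to_numpy(dtype=float) / (lib[None, :] * lengths[:, None])
    return pd.DataFrame(vals, index=matrix.genes, columns=matrix.samples)


def ac_test(x, y, n1, n2):
    """Two-sided Audic-Claverie p-value for tag counts x (library size n1)
    versus y (library size n2).  Vectorised over x and y.

    The predictive distribution conditions on one library's count; to make
    the statistic exactly orientation-invariant the conditioning side is
    chosen canonically as the larger library (larger count on ties), so
    ``ac_test(x, y, n1, n2) == ac_test(y, x, n2, n1)`` always holds.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if np.any(x < 0) or np.any(y < 0):
        raise DomainError("tag counts must be >= 0")
    if n1 <= 0 or n2 <= 0:
        raise DomainError("library sizes must be > 0")
    swap = (n2 > n1) | ((n2 == n1) & (y > x))
    cond = np.where(swap, y, x)       # conditioning count
    other = np.where(swap, x, y)      # count whose tail is evaluated
    n_cond = np.where(swap, n2, n1)
    n_other = np.where(swap, n1, n2)
    p_succ = n_cond / (n_cond + n_other)
    lower = nbinom.cdf(other, cond + 1, p_succ)          # P(Y <= other)
    upper = nbinom.sf(other - 1, cond + 1, p_succ)       # P(Y >= other)
    out = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return out if out.ndim else float(out)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any(pvals < 0) or np.any(pvals > 1) or np.any(np.isnan(pvals)):
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def call_degs(
    matrix: ExpressionMatrix,
    side_a: Sequence[str],
    side_b: Sequence[str],
    cfg: DegConfig | None = None,
) -> pd.DataFrame:
    """Call DEGs between two replicate groups.

    Replicate counts are pooled by summation per side before the tag test;
    genes with zero counts on both sides are excluded from testing entirely.
    Fold change is the ratio of pseudocounted mean RPKMs oriented so
    FC >= 1, with ``direction`` "up" meaning higher in ``side_a``.  Returns
    a DegTable: one row per tested gene with counts, RPKMs, fold change,
    direction, p, q, magnitude bin and the significance flag.
    """
    cfg = cfg or DegConfig()
    side_a = list(side_a)
    side_b = list(side_b)
    if not side_a or not side_b:
        raise ConfigError("both sample groups must be non-empty")
    if set(side_a) & set(side_b):
        raise ConfigError("sample groups must be disjoint")
    missing = (set(side_a) | set(side_b)) - set(matrix.samples)
    if missing:
        raise ConfigError(f"unknown samples: {sorted(missing)}")

    x = matrix.counts[side_a].sum(axis=1)
    y = matrix.counts[side_b].sum(axis=1)
    n1 = int(matrix.library_sizes[side_a].sum())
    n2 = int(matrix.library_sizes[side_b].sum())
    tested = (x + y) > 0

    rpkm = compute_rpkm(matrix)
    mean_a = rpkm[side_a].mean(axis=1)
    mean_b = rpkm[side_b].mean(axis=1)
    pc = cfg.pseudocount_rpkm
    ratio = (mean_a + pc) / (mean_b + pc)
    fc = np.where(ratio >= 1.0, ratio, 1.0 / ratio)
    direction = np.where(ratio >= 1.0, "up", "down")

    table = pd.DataFrame(
        {
            "count_a": x,
            "count_b": y,
            "rpkm_a": mean_a,
            "rpkm_b": mean_b,
            "fold_change": fc,
            "direction": direction,
        },
        index=matrix.genes,
    )
    table = table[tested].copy()
    pvals = ac_test(table["count_a"].to_numpy(), table["count_b"].to_numpy(), n1, n2)
    qvals = bh_adjust(pvals)
    table["pvalue"] = pvals
    table["qvalue"] = qvals
    table["significant"] = (table["fold_change"] > cfg.fold_change_threshold) & (
        table["qvalue"] <= cfg.fdr_threshold
    )
    table["bin"] = _bin_fold_changes(table["fold_change"].to_numpy())
    table.index.name = "gene_id"
    table.attrs["library_size_a"] = n1
    table.attrs["library_size_b"] = n2
    table.attrs["excluded_zero"] = int((~tested).sum())
    return table


def significant_degs(deg_table: pd.DataFrame) -> pd.DataFrame:
    return deg_table[deg_table["significant"]]


def _bin_fold_changes(fc: np.ndarray) -> np.ndarray:
    """Right-closed magnitude bins; values at or below the lowest edge get ''."""
    labels = np.full(fc.shape, "", dtype=object)
    edges = (*BIN_EDGES, np.inf)
    for lo, hi, label in zip(edges[:-1], edges[1:], BIN_LABELS):
        labels[(fc > lo) & (fc <= hi)] = label
    return labels


def summarize_fold_bins(degs: pd.DataFrame) -> dict:
    """Bin significant DEGs by fold-change magnitude and direction.

    Bins are (2, 10], (10, 100], (100, 1000], (1000, inf); FC = 10 falls in
    2-10 (right-closed).  Input rows must all carry FC > 2 and a direction
    (i.e. be significant calls); otherwise a consistency error is raised.
    Returns nested counts with per-direction and grand totals.
    """
    if "significant" in degs.columns:
        degs = degs[degs["significant"]]
    fc = degs["fold_change"].to_numpy(dtype=float)
    if np.any(fc <= BIN_EDGES[0]):
        raise ConsistencyError(
            f"record with fold change <= {BIN_EDGES[0]:g} should not have been called"
        )
    out: dict = {}
    for direction in ("up", "down"):
        sub = degs[degs["direction"] == direction]
        bins = _bin_fold_changes(sub["fold_change"].to_numpy(dtype=float))
        out[direction] = {label: int((bins == label).sum()) for label in BIN_LABELS}
        out[direction]["total"] = int(len(sub))
    out["total"] = out["up"]["total"] + out["down"]["total"]
    return out


_BIN_REPRESENTATIVE_FC = {"2-10": 5.0, "10-100": 50.0, "100-1000": 500.0, ">1000": 5000.0}


def degs_from_bin_counts(bin_counts: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Reconstruct a minimal DegTable from published per-bin DEG counts.

    ``bin_counts`` maps direction ("up"/"down") to {bin label: count}.  Each
    reported gene becomes one row with a representative fold change inside
    its bin, so binned summaries of the reconstruction reproduce the
    reported marginals.  Used for worked examples against printed tables.
    """
    rows = []
    i = 0
    for direction in ("up", "down"):
        for label in BIN_LABELS:
            for _ in range(int(bin_counts.get(direction, {}).get(label, 0))):
                i += 1
                rows.append(
                    {"gene_id": f"reported_{i:05d}", "fold_change":
                     _BIN_REPRESENTATIVE_FC[label], "direction": direction,
                     "significant": True}
                )
    table = pd.DataFrame(rows, columns=["gene_id", "fold_change", "direction",
                                        "significant"])
    return table.set_index("gene_id")
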