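"""Candidate-gene logic: DEG-set overlap across conditions and SNP x DEG
integration.

A candidate gene is one that contains at least one high-probability SNP
called under both growth conditions; its evidence is strengthened when it is
also differentially expressed between the bulks.  Genes significant in both
condition contrasts are classified by their direction pair: concordant, or
opposite (down-then-up / up-then-down, ordering the contrasts as supplied).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .formats_io import GeneModel

OVERLAP_CLASSES = ("concordant", "opposite_down_then_up", "opposite_up_then_down")


@dataclass
class OverlapClassification:
    """Genes significant in both contrasts, classified by direction pair."""

    frame: pd.DataFrame  # gene_id, direction_a, direction_b, overlap_class
    counts: dict[str, int]

    @property
    def n_overlap(self) -> int:
        return len(self.frame)


def overlap_deg_sets(deg_a: pd.DataFrame, deg_b: pd.DataFrame) -> OverlapClassification:
    """Intersect the significant gene sets of two DEG contrasts.

    Only genes significant in BOTH contrasts enter the overlap.  A strict
    direction flip yields an opposite class; otherwise concordant.  The
    class counts always partition the overlap.
    """
    sig_a = deg_a[deg_a["significant"]][["direction"]].rename(
        columns={"direction": "direction_a"}
    )
    sig_b = deg_b[deg_b["significant"]][["direction"]].rename(
        columns={"direction": "direction_b"}
    )
    merged = sig_a.join(sig_b, how="inner").reset_index()
    flips_down_up = (merged["direction_a"] == "down") & (merged["direction_b"] == "up")
    flips_up_down = (merged["direction_a"] == "up") & (merged["direction_b"] == "down")
    merged["overlap_class"] = np.select(
        [flips_down_up, flips_up_down],
        ["opposite_down_then_up", "opposite_up_then_down"],
        default="concordant",
    )
    merged = merged.sort_values("gene_id", kind="mergesort").reset_index(drop=True)
    counts = {cls: int((merged["overlap_class"] == cls).sum()) for cls in OVERLAP_CLASSES}
    counts["overlap"] = len(merged)
    return OverlapClassification(frame=merged, counts=counts)


def integrate_snp_deg(
    snp_gene_assignments: pd.DataFrame,
    deg_tables: Mapping[str, pd.DataFrame],
    genes: Sequence[GeneModel] | None = None,
) -> pd.DataFrame:
    """Build the ranked candidate-gene table.

    ``snp_gene_assignments`` is the output of
    :func:`bsrseq.bsa_linkage.assign_snps_to_genes` run on the
    cross-condition overlap SNP set: rows of (chrom, pos, ..., gene_id).
    Each distinct SNP-bearing gene appears exactly once, annotated with its
    DEG status per contrast, and ranked by (number of contrasts significant,
    maximum SNP posterior, SNP count) descending with ties broken by gene id.
    """
    genic = snp_gene_assignments.dropna(subset=["gene_id"])
    post_cols = [c for c in genic.columns if c.startswith("posterior")]
    records = []
    for gene_id, grp in genic.groupby("gene_id", sort=True):
        max_post = float(grp[post_cols].to_numpy().max()) if post_cols else float("nan")
        rec = {
            "gene_id": gene_id,
            "chrom": grp["chrom"].iloc[0],
            "n_snps": len(grp),
            "snp_positions": ",".join(str(p) for p in sorted(grp["pos"])),
            "max_posterior": max_post,
        }
        n_sig = 0
        for label, deg in deg_tables.items():
            if gene_id in deg.index and bool(deg.loc[gene_id, "significant"]):
                n_sig += 1
                rec[f"significant_{label}"] = True
                rec[f"direction_{label}"] = deg.loc[gene_id, "direction"]
            else:
                rec[f"significant_{label}"] = False
                rec[f"direction_{label}"] = None
        rec["n_contrasts_significant"] = n_sig
        records.append(rec)
    columns = ["gene_id", "chrom", "n_snps", "snp_positions", "max_posterior"]
    for label in deg_tables:
        columns += [f"significant_{label}", f"direction_{label}"]
    columns.append("n_contrasts_significant")
    table = pd.DataFrame(records, columns=columns)
    if genes is not None:
        spans = {g.gene_id: (g.start, g.end) for g in genes}
        table["start"] = table["gene_id"].map(lambda g: spans.get(g, (None, None))[0])
        table["end"] = table["gene_id"].map(lambda g: spans.get(g, (None, None))[1])
    table = table.sort_values(
        by=["n_contrasts_significant", "max_posterior", "n_snps", "gene_id"],
        ascending=[False, False, False, True],
        kind="mergesort",
    )
    return table.reset_index(drop=True)


def genes_in_region(
    genes: Sequence[GeneModel], chrom: str, start: int, end: int
) -> list[GeneModel]:
    """Genes whose 1-based inclusive span intersects [start, end] on chrom.

    A single-bp touch counts as intersection.  An unknown chromosome yields
    an empty list with a warning.
    """
    if start > end:
        raise ConfigError(f"region start {start} > end {end}")
    known = {g.chrom for g in genes}
    if chrom not in known:
        warnings.warn(f"chromosome {chrom!r} not present in the gene set", stacklevel=2)
        return []
    hits = [g for g in genes if g.chrom == chrom and g.start <= end and g.end >= start]
    return sorted(hits, key=lambda g: (g.start, g.end, g.gene_id))


def flag_candidates_in_region(
    candidates: pd.DataFrame,
    genes: Sequence[GeneModel],
    chrom: str,
    start: int,
    end: int,
) -> pd.DataFrame:
    """Add an in-interval flag for a user-supplied marker interval."""
    inside = {g.gene_id for g in genes_in_region(genes, chrom, start, end)}
    out = candidates.copy()
    out["in_region"] = out["gene_id"].isin(inside)
    return out
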