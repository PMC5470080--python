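"""Synthetic two-bulk BSR-seq data with ground truth.

The generator emulates the study design the analysis assumes: a tolerant
bulk pooled from 8 homozygous inbred lines and a sensitive bulk from 10,
with a single causal locus at which every tolerant line carries one allele
and every sensitive line the other.  Because the lines are an unrelated
germplasm panel rather than a mapping cross, allele-state coupling to the
causal locus decays with genomic distance like linkage disequilibrium: a
line carries the allele coupled to its own causal-locus allele with
probability ``c(d) = 0.5 + 0.5 * exp(-d / ld_decay_length)`` on the causal
chromosome and ``c = 0.5`` elsewhere.  Bulk allele frequencies are carrier
fractions, so they live on the lattice k/m for bulk size m.

Sequencing is modelled per (site, bulk, condition) cell as Poisson depth
with binomial allele sampling at ``f (1 - eps) + (1 - f) eps`` for focal-type
reads; of the remaining reads, each lands on a third base with probability
``eps / 2``, which is the simplest contamination able to violate the
two-SNP-type site filter.  Both conditions reuse the same genotypes - only
sampling noise differs - reproducing the expectation that true linkage
signals recur across conditions.

Expression is 2 pools x 2 conditions x ``n_replicates`` negative-binomial
replicates with log-uniform baseline abundances and planted signed
``2**de_log2fc`` effects in a designated sample group.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .formats_io import BASES, AlleleCountTable, GeneModel
from .expression_deg import ExpressionMatrix

POOLS = ("tolerant", "sensitive")
CONDITIONS = ("normal", "waterlogged")


@dataclass
class SimulationConfig:
    """Study-design and noise parameters of the generator.

    Defaults mirror the emulated design: 8 tolerant / 10 sensitive lines,
    three biological replicates per pool x condition, ~50x per-cell allele
    depth, 1% base error, and per-gene sequencing coverage of roughly 1000
    reads (2M reads per replicate over 2000 genes).
    """

    n_tolerant_lines: int = 8
    n_sensitive_lines: int = 10
    chromosomes: tuple[tuple[str, int], ...] = (
        ("chr1", 80_000_000),
        ("chr2", 60_000_000),
        ("chr3", 60_000_000),
    )
    n_snps: int = 2000
    causal_chrom: str = "chr1"
    causal_pos: int = 40_000_000
    ld_decay_length: float = 10_000_000.0
    linked_cutoff: float = 0.95
    mean_depth: float = 50.0
    base_error: float = 0.01
    n_replicates: int = 3
    n_genes: int = 2000
    n_de_genes: int = 100
    de_log2fc: float = 3.0
    de_group: str = "tolerant"
    nb_dispersion: float = 0.01
    library_size_mean: float = 2_000_000.0
    gene_length_range: tuple[int, int] = (500, 5000)
    causal_gene_de: bool = True
    seed: int = 42

    def __post_init__(self):
        if self.n_tolerant_lines < 1 or self.n_sensitive_lines < 1:
            raise ConfigError("bulk line counts must be >= 1")
        if self.ld_decay_length <= 0:
            raise ConfigError("ld_decay_length must be > 0")
        if not 0.0 <= self.base_error < 0.5:
            raise ConfigError("base_error must lie in [0, 0.5)")
        if self.mean_depth < 0:
            raise ConfigError("mean_depth must be >= 0")
        if self.n_de_genes > self.n_genes:
            raise ConfigError("n_de_genes cannot exceed n_genes")
        if self.causal_chrom not in {name for name, _ in self.chromosomes}:
            raise ConfigError(
                f"causal chromosome {self.causal_chrom!r} not among the listed chromosomes"
            )
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")


@dataclass
class PanelTruth:
    """Ground truth of the simulated panel.

    ``snps`` columns: chrom, pos, type1 (tolerant-coupled base), type2,
    type3 (error sink), coupling c, linked flag, f_t, f_s.  Genotype arrays
    are carrier indicators of type1 per line.
    """

    snps: pd.DataFrame
    tolerant_genotypes: np.ndarray  # (n_tolerant_lines, n_snps) bool
    sensitive_genotypes: np.ndarray  # (n_sensitive_lines, n_snps) bool
    causal_chrom: str
    causal_pos: int
    causal_index: int


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, *stream])


def simulate_panel(cfg: SimulationConfig) -> PanelTruth:
    """Draw SNP positions, per-line genotypes, and bulk allele frequencies.

    One SNP is pinned to the causal locus itself (c = 1 there, so f_t = 1
    and f_s = 0 exactly); the rest are uniform per chromosome with
    chromosome choice proportional to length.  Deterministic given the seed.
    """
    rng = _rng(cfg.seed, 0)
    names = [name for name, _ in cfg.chromosomes]
    lengths = np.array([length for _, length in cfg.chromosomes], dtype=float)
    chrom_idx = rng.choice(len(names), size=cfg.n_snps - 1, p=lengths / lengths.sum())
    pos = rng.integers(1, lengths[chrom_idx].astype(np.int64) + 1)
    chrom = np.array([names[i] for i in chrom_idx], dtype=object)
    chrom = np.concatenate([[cfg.causal_chrom], chrom])
    pos = np.concatenate([[cfg.causal_pos], pos]).astype(np.int64)
    # sites must be unique per (chrom, pos); redraw any collisions
    for _ in range(1000):
        seen: dict[tuple, int] = {}
        dup = []
        for i, key in enumerate(zip(chrom, pos)):
            if key in seen:
                dup.append(i)
            else:
                seen[key] = i
        if not dup:
            break
        for i in dup:
            length = int(lengths[names.index(chrom[i])])
            pos[i] = rng.integers(1, length + 1)
    else:
        raise ConfigError("could not place n_snps unique sites; "
                          "chromosomes too short for n_snps")

    d = np.abs(pos - cfg.causal_pos)
    on_causal = chrom == cfg.causal_chrom
    coupling = np.where(
        on_causal, 0.5 + 0.5 * np.exp(-d / cfg.ld_decay_length), 0.5
    )

    # conditional on its causal-locus allele, each line carries the
    # causally-coupled SNP allele with probability c
    tol = rng.random((cfg.n_tolerant_lines, cfg.n_snps)) < coupling[None, :]
    sen = rng.random((cfg.n_sensitive_lines, cfg.n_snps)) < (1.0 - coupling)[None, :]
    f_t = tol.mean(axis=0)
    f_s = sen.mean(axis=0)

    base_triplets = np.array(
        [rng.choice(4, size=3, replace=False) for _ in range(cfg.n_snps)]
    )
    snps = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "type1": [BASES[i] for i in base_triplets[:, 0]],
            "type2": [BASES[i] for i in base_triplets[:, 1]],
            "type3": [BASES[i] for i in base_triplets[:, 2]],
            "coupling": coupling,
            "linked": on_causal & (coupling >= cfg.linked_cutoff),
            "f_t": f_t,
            "f_s": f_s,
        }
    )
    return PanelTruth(
        snps=snps,
        tolerant_genotypes=tol,
        sensitive_genotypes=sen,
        causal_chrom=cfg.causal_chrom,
        causal_pos=cfg.causal_pos,
        causal_index=0,
    )


def simulate_allele_counts(
    truth: PanelTruth, cfg: SimulationConfig, condition: str
) -> AlleleCountTable:
    """Draw an allele-count table for one condition.

    Depth per (site, bulk) cell is Poisson(mean_depth); focal-type reads are
    binomial at ``f (1 - eps) + (1 - f) eps``; of the remainder, each read is
    miscalled to the third base with probability eps/2.  Conditions share
    genotypes but draw depths independently.
    """
    rng = _rng(cfg.seed, 1, zlib.crc32(condition.encode()))
    eps = cfg.base_error
    n = len(truth.snps)
    frames = []
    freqs = {"tolerant": truth.snps["f_t"].to_numpy(),
             "sensitive": truth.snps["f_s"].to_numpy()}
    base_idx = {b: i for i, b in enumerate(BASES)}
    type_cols = [truth.snps[t].map(base_idx).to_numpy() for t in ("type1", "type2", "type3")]
    for bulk in POOLS:
        f = freqs[bulk]
        depth = rng.poisson(cfg.mean_depth, size=n)
        q = f * (1 - eps) + (1 - f) * eps
        n1 = rng.binomial(depth, q)
        n3 = rng.binomial(depth - n1, eps / 2.0)
        n2 = depth - n1 - n3
        counts = np.zeros((n, 4), dtype=np.int64)
        rows = np.arange(n)
        np.add.at(counts, (rows, type_cols[0]), n1)
        np.add.at(counts, (rows, type_cols[1]), n2)
        np.add.at(counts, (rows, type_cols[2]), n3)
        frame = pd.DataFrame(counts, columns=list(BASES))
        frame.insert(0, "condition", condition)
        frame.insert(0, "bulk", bulk)
        frame.insert(0, "pos", truth.snps["pos"].to_numpy())
        frame.insert(0, "chrom", truth.snps["chrom"].to_numpy())
        frames.append(frame)
    return AlleleCountTable(pd.concat(frames, ignore_index=True))


def nb_counts(rng: np.random.Generator, mean, dispersion: float, size=None) -> np.ndarray:
    """Negative-binomial draws parametrised by mean and dispersion alpha,
    with variance ``mu + alpha * mu**2``; alpha = 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def sample_name(pool: str, condition: str, replicate: int) -> str:
    return f"{pool}_{condition}_{replicate}"


def simulate_expression(
    cfg: SimulationConfig, force_de: Sequence[int] | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate the replicate count matrix and the planted-DE truth.

    Baseline relative abundances are log-uniform over three decades; the
    ``n_de_genes`` planted genes receive a ``2**(sign * de_log2fc)``
    multiplier in every sample group matching all underscore-separated
    tokens of ``cfg.de_group`` (e.g. ``"tolerant"`` or
    ``"tolerant_waterlogged"``).  ``force_de`` gene indices are always among
    the planted set.  Returns the matrix and a truth table of
    (gene_id, log2fc).
    """
    rng = _rng(cfg.seed, 2)
    n = cfg.n_genes
    gene_ids = pd.Index([f"g{i + 1:05d}" for i in range(n)], name="gene_id")
    rel = 10.0 ** rng.uniform(0.0, 3.0, size=n)
    lengths = pd.Series(
        rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, size=n),
        index=gene_ids,
    )

    force_de = list(force_de or [])
    if len(force_de) > cfg.n_de_genes:
        raise ConfigError("more forced DE genes than n_de_genes")
    forced = set(force_de)
    pool_pick = [i for i in rng.permutation(n) if i not in forced]
    de_idx = np.array(force_de + pool_pick[: cfg.n_de_genes - len(force_de)],
                      dtype=np.int64)
    signs = rng.choice([-1.0, 1.0], size=len(de_idx))
    log2fc = np.zeros(n)
    log2fc[de_idx] = signs * cfg.de_log2fc

    tokens = set(cfg.de_group.split("_"))
    columns = {}
    for pool in POOLS:
        for condition in CONDITIONS:
            affected = tokens <= {pool, condition}
            mu_rel = rel * (2.0 ** log2fc if affected else 1.0)
            p = mu_rel / mu_rel.sum()
            for rep in range(1, cfg.n_replicates + 1):
                lib = rng.poisson(cfg.library_size_mean)
                columns[sample_name(pool, condition, rep)] = nb_counts(
                    rng, p * lib, cfg.nb_dispersion
                )
    counts = pd.DataFrame(columns, index=gene_ids).astype(np.int64)
    matrix = ExpressionMatrix(counts=counts, lengths=lengths)
    truth = pd.DataFrame(
        {"gene_id": gene_ids[de_idx], "log2fc": log2fc[de_idx], "group": cfg.de_group}
    ).sort_values("gene_id", kind="mergesort").reset_index(drop=True)
    return matrix, truth


def simulate_genes(cfg: SimulationConfig) -> tuple[list[GeneModel], str]:
    """Place ``n_genes`` gene models on the chromosomes.

    Spans are uniform with lengths from ``gene_length_range``; one randomly
    chosen gene is re-anchored to straddle the causal locus so the causal
    SNP always falls inside a gene model.  Returns (genes, causal_gene_id);
    gene ids match the expression matrix's.
    """
    rng = _rng(cfg.seed, 3)
    names = [name for name, _ in cfg.chromosomes]
    lengths = np.array([length for _, length in cfg.chromosomes], dtype=np.int64)
    chrom_idx = rng.choice(len(names), size=cfg.n_genes, p=lengths / lengths.sum())
    glen = rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1,
                        size=cfg.n_genes)
    start = rng.integers(1, np.maximum(lengths[chrom_idx] - glen, 1) + 1)
    strand = rng.choice(["+", "-"], size=cfg.n_genes)

    causal_i = int(rng.integers(cfg.n_genes))
    chrom_idx[causal_i] = names.index(cfg.causal_chrom)
    start[causal_i] = max(1, cfg.causal_pos - int(glen[causal_i]) // 2)

    genes = [
        GeneModel(
            gene_id=f"g{i + 1:05d}",
            chrom=names[chrom_idx[i]],
            start=int(start[i]),
            end=int(start[i] + glen[i] - 1),
            strand=str(strand[i]),
        )
        for i in range(cfg.n_genes)
    ]
    return genes, f"g{causal_i + 1:05d}"


@dataclass
class SyntheticDataset:
    """Everything one pipeline run consumes, plus ground truth."""

    config: SimulationConfig
    truth: PanelTruth
    allele_counts: dict[str, AlleleCountTable]  # per condition
    expression: ExpressionMatrix
    de_truth: pd.DataFrame
    genes: list[GeneModel]
    causal_gene_id: str


def simulate_dataset(cfg: SimulationConfig | None = None) -> SyntheticDataset:
    """Full simulation: panel, per-condition allele counts, genes, expression.

    When ``cfg.causal_gene_de`` the causal-locus gene is planted among the
    DE genes (the emulated scenario is a causal gene that is both
    polymorphic between bulks and expression-responsive).
    """
    cfg = cfg or SimulationConfig()
    truth = simulate_panel(cfg)
    counts = {cond: simulate_allele_counts(truth, cfg, cond) for cond in CONDITIONS}
    genes, causal_gene_id = simulate_genes(cfg)
    force = None
    if cfg.causal_gene_de and cfg.n_de_genes > 0:
        force = [int(causal_gene_id[1:]) - 1]
    expression, de_truth = simulate_expression(cfg, force_de=force)
    return SyntheticDataset(
        config=cfg,
        truth=truth,
        allele_counts=counts,
        expression=expression,
        de_truth=de_truth,
        genes=genes,
        causal_gene_id=causal_gene_id,
    )


def simulate_mixture_counts(
    n_sites: int = 1000,
    linked_fraction: float = 0.10,
    depth: float = 100.0,
    seed: int = 7,
) -> pd.DataFrame:
    """Two-component calibration panel for prior estimation.

    A ``linked_fraction`` of sites is fully divergent (f_t = 1, f_s = 0);
    the rest share one frequency drawn uniformly, matching the unlinked
    hypothesis exactly.  Depths are Poisson per bulk.  Columns:
    a_t, b_t, a_s, b_s, linked.
    """
    rng = np.random.default_rng([seed, 4])
    n_linked = int(round(n_sites * linked_fraction))
    linked = np.zeros(n_sites, dtype=bool)
    linked[:n_linked] = True
    f_shared = rng.uniform(0.0, 1.0, size=n_sites)
    f_t = np.where(linked, 1.0, f_shared)
    f_s = np.where(linked, 0.0, f_shared)
    d_t = rng.poisson(depth, size=n_sites)
    d_s = rng.poisson(depth, size=n_sites)
    a_t = rng.binomial(d_t, f_t)
    a_s = rng.binomial(d_s, f_s)
    return pd.DataFrame(
        {"a_t": a_t, "b_t": d_t - a_t, "a_s": a_s, "b_s": d_s - a_s, "linked": linked}
    )
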