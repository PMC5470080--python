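"""Readers and writers for the external formats used by the pipeline.

Allele-depth tables (TSV or VCF with per-sample allelic depths), gene models
(GFF3), gene-level count matrices (TSV), and FASTQ with the numeric read-QC
filter.  Internal genomic coordinates are kept in each format's native
convention at the boundary: GFF3 and VCF positions are 1-based inclusive and
are stored as such on the in-memory objects, so a span written back out is
byte-identical to the span read in.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    DuplicateRecordError,
    FormatError,
)

BASES = ("A", "C", "G", "T")

_TABLE_KEY = ["chrom", "pos", "bulk", "condition"]
_TABLE_COLUMNS = _TABLE_KEY + list(BASES)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene-level feature with a 1-based inclusive genomic span."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.gene_id:
            raise FormatError("gene model requires a non-empty gene identifier")
        if self.end < self.start:
            raise FormatError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )
        if self.start < 1:
            raise FormatError(f"gene {self.gene_id}: 1-based start must be >= 1")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class ReadQcConfig:
    """Thresholds for the per-read quality filter.

    A read is discarded iff its fraction of ambiguous (N) bases exceeds
    ``max_n_fraction``, or the fraction of bases with phred quality at or
    below ``low_quality_phred`` exceeds ``max_low_quality_fraction``.
    """

    max_n_fraction: float = 0.05
    low_quality_phred: int = 10
    max_low_quality_fraction: float = 0.20
    phred_offset: int = 33

    def __post_init__(self):
        for name in ("max_n_fraction", "max_low_quality_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.low_quality_phred < 0:
            raise ConfigError("low_quality_phred must be >= 0")
        if self.phred_offset not in (33, 64):
            raise ConfigError("phred_offset must be 33 (Sanger) or 64 (Illumina 1.3+)")


@dataclass
class SiteCounts:
    """Observed SNP-type read counts for one site.

    ``cells`` maps ``(bulk, condition)`` to a base -> count mapping; the
    pooled per-type totals and the site total are derived, never stored, so
    they cannot drift out of sync.
    """

    chrom: str
    pos: int
    cells: dict[tuple[str, str], dict[str, int]]

    def __post_init__(self):
        for cell, counts in self.cells.items():
            for base, n in counts.items():
                if n < 0:
                    raise FormatError(
                        f"{self.chrom}:{self.pos} cell {cell}: negative count for {base}"
                    )

    @property
    def pooled(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for counts in self.cells.values():
            for base, n in counts.items():
                out[base] = out.get(base, 0) + int(n)
        return out

    @property
    def total(self) -> int:
        return sum(self.pooled.values())

    def pooled_for(self, condition: str | None = None) -> dict[str, int]:
        """Pool counts across cells, optionally restricted to one condition."""
        if condition is None:
            return self.pooled
        out: dict[str, int] = {}
        for (_, cond), counts in self.cells.items():
            if cond != condition:
                continue
            for base, n in counts.items():
                out[base] = out.get(base, 0) + int(n)
        return out


class AlleleCountTable:
    """Per-site, per-(bulk, condition) counts of observed SNP-types.

    Backed by a long-format DataFrame with columns
    ``chrom, pos, bulk, condition, A, C, G, T`` and one row per cell.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _TABLE_COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"allele-count table lacks columns: {missing}")
        frame = frame.loc[:, _TABLE_COLUMNS].copy()
        for base in BASES:
            col = pd.to_numeric(frame[base], errors="coerce")
            if col.isna().any():
                bad = int(frame.index[col.isna()][0])
                raise FormatError(f"non-numeric count in column {base}, row {bad}")
            if (col < 0).any():
                bad = int(frame.index[col < 0][0])
                raise FormatError(f"negative count in column {base}, row {bad}")
            if (col != col.round()).any():
                bad = int(frame.index[col != col.round()][0])
                raise FormatError(f"non-integer count in column {base}, row {bad}")
            frame[base] = col.astype(np.int64)
        frame["pos"] = pd.to_numeric(frame["pos"]).astype(np.int64)
        dup = frame.duplicated(subset=_TABLE_KEY)
        if dup.any():
            key = frame.loc[dup.idxmax(), _TABLE_KEY].tolist()
            raise DuplicateRecordError(f"duplicate (chrom,pos,bulk,condition) record: {key}")
        self.frame = frame.sort_values(_TABLE_KEY, kind="mergesort").reset_index(drop=True)
        self.load_summary: dict[str, int] = {}

    # -- introspection ------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.frame[["chrom", "pos"]].drop_duplicates())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.frame["condition"].unique())

    @property
    def bulks(self) -> list[str]:
        return sorted(self.frame["bulk"].unique())

    def site_keys(self) -> pd.DataFrame:
        return self.frame[["chrom", "pos"]].drop_duplicates().reset_index(drop=True)

    def pooled(self, condition: str | None = None) -> pd.DataFrame:
        """Per-site base counts pooled over cells (optionally one condition)."""
        frame = self.frame
        if condition is not None:
            frame = frame[frame["condition"] == condition]
        return frame.groupby(["chrom", "pos"], sort=True)[list(BASES)].sum()

    def iter_sites(self) -> Iterator[SiteCounts]:
        for (chrom, pos), grp in self.frame.groupby(["chrom", "pos"], sort=True):
            cells = {
                (row.bulk, row.condition): {b: int(getattr(row, b)) for b in BASES}
                for row in grp.itertuples()
            }
            yield SiteCounts(chrom=chrom, pos=int(pos), cells=cells)

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# allele-count reading
# ---------------------------------------------------------------------------


def read_allele_counts(path: str | os.PathLike, dialect: str = "tsv") -> AlleleCountTable:
    """Load an allele-count table from TSV or VCF.

    The TSV dialect is the canonical interchange: header columns
    ``chrom pos bulk condition A C G T``.  The VCF dialect reads only the
    per-sample allelic-depth (AD) field from samples named ``bulk_condition``;
    genotype likelihoods are never consulted.  Cells absent for a site that
    other sites carry are recorded as zero and counted in ``load_summary``.
    """
    if dialect == "tsv":
        table = _read_counts_tsv(path)
    elif dialect == "vcf":
        table = _read_counts_vcf(path)
    else:
        raise ConfigError(f"unknown allele-count dialect: {dialect!r}")
    _complete_cells(table)
    return table


def _read_counts_tsv(path) -> AlleleCountTable:
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if frame.isna().any().any():
        line = int(frame.index[frame.isna().any(axis=1)][0]) + 2  # header is line 1
        raise FormatError(f"{path}: malformed row at line {line}")
    try:
        return AlleleCountTable(frame)
    except FormatError as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def _read_counts_vcf(path) -> AlleleCountTable:
    import pysam

    rows = []
    skipped = 0
    with pysam.VariantFile(os.fspath(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                skipped += 1
                continue
            for sample_name, sample in rec.samples.items():
                if "_" not in sample_name:
                    raise FormatError(
                        f"VCF sample {sample_name!r} is not named bulk_condition"
                    )
                bulk, condition = sample_name.split("_", 1)
                ad = sample.get("AD")
                if ad is None or ad[0] is None:
                    continue
                counts = dict.fromkeys(BASES, 0)
                counts[ref] = int(ad[0])
                counts[alt] = int(ad[1])
                rows.append(
                    {"chrom": rec.chrom, "pos": rec.pos, "bulk": bulk,
                     "condition": condition, **counts}
                )
    frame = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    table = AlleleCountTable(frame)
    table.load_summary["skipped_non_snp"] = skipped
    return table


def _complete_cells(table: AlleleCountTable) -> None:
    """Fill missing (site, cell) combinations with zero counts."""
    frame = table.frame
    if frame.empty:
        table.load_summary.setdefault("missing_cells", 0)
        return
    sites = frame[["chrom", "pos"]].drop_duplicates()
    cells = frame[["bulk", "condition"]].drop_duplicates()
    full = sites.merge(cells, how="cross")
    merged = full.merge(frame, on=_TABLE_KEY, how="left")
    n_missing = int(merged[list(BASES)].isna().any(axis=1).sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} missing (site, bulk, condition) cells recorded as zero",
            stacklevel=3,
        )
        merged[list(BASES)] = merged[list(BASES)].fillna(0).astype(np.int64)
        summary = table.load_summary
        table.__init__(merged)
        table.load_summary = summary
    table.load_summary["missing_cells"] = n_missing
    table.load_summary["n_sites"] = table.n_sites


# ---------------------------------------------------------------------------
# gene models (GFF3)
# ---------------------------------------------------------------------------


def read_gene_models(path: str | os.PathLike, feature_type: str = "gene") -> list[GeneModel]:
    """Read gene-level features from GFF3 into GeneModel records.

    Coordinates stay 1-based inclusive as in the file.  An empty file yields
    an empty list.  A feature without an ID (or gene_id) attribute, or with
    end < start, is a format error.
    """
    import gffutils

    with open(path) as fh:
        has_features = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_features:
        return []
    try:
        db = gffutils.create_db(
            os.fspath(path), ":memory:", force=True, keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise FormatError(f"{path}: cannot parse GFF3 ({exc})") from exc
    genes = []
    for feat in db.features_of_type(feature_type):
        gene_id = feat.attributes.get("ID", feat.attributes.get("gene_id", [None]))[0]
        if gene_id is None:
            raise FormatError(f"{path}: {feature_type} feature at "
                              f"{feat.seqid}:{feat.start} lacks an identifier")
        if feat.end < feat.start:
            raise FormatError(f"{path}: gene {gene_id} has end < start")
        strand = feat.strand if feat.strand in ("+", "-") else "."
        genes.append(GeneModel(gene_id, feat.seqid, feat.start, feat.end, strand))
    ids = [g.gene_id for g in genes]
    if len(ids) != len(set(ids)):
        raise DuplicateRecordError(f"{path}: duplicated gene identifier")
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str | os.PathLike,
                      feature_type: str = "gene") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\tbsrseq\t{feature_type}\t{g.start}\t{g.end}\t.\t"
                f"{g.strand if g.strand in '+-' else '.'}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def read_count_matrix(
    path: str | os.PathLike,
    length_column: str = "length",
    library_sizes: Mapping[str, int] | str | os.PathLike | None = None,
) -> "ExpressionMatrix":
    """Read a gene x sample count matrix from TSV.

    First column holds gene ids, an optional ``length`` column the gene
    length in bp; all remaining columns are samples.  Library sizes default
    to column sums unless an explicit mapping or a two-column sidecar TSV
    (sample, library_size) is supplied.
    """
    from .expression_deg import ExpressionMatrix

    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if frame.isna().any().any():
        raise FormatError(f"{path}: ragged or incomplete row")
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise DuplicateRecordError(f"{path}: duplicated gene id {dup!r}")
    lengths = None
    if length_column in frame.columns:
        lengths = pd.to_numeric(frame[length_column]).astype(np.int64)
        frame = frame.drop(columns=[length_column])
    counts = frame.apply(pd.to_numeric, errors="coerce")
    if counts.isna().any().any():
        raise FormatError(f"{path}: non-numeric count")
    if ((counts != counts.round()).any().any()) or (counts < 0).any().any():
        raise FormatError(f"{path}: counts must be non-negative integers")
    counts = counts.astype(np.int64)
    lib = None
    if library_sizes is not None:
        if isinstance(library_sizes, (str, os.PathLike)):
            side = pd.read_csv(library_sizes, sep="\t", index_col=0).iloc[:, 0]
            lib = side.reindex(counts.columns)
            if lib.isna().any():
                raise FormatError("library-size sidecar misses samples "
                                  f"{list(lib.index[lib.isna()])}")
        else:
            lib = pd.Series(library_sizes).reindex(counts.columns)
            if lib.isna().any():
                raise FormatError("library-size mapping misses samples")
        lib = lib.astype(np.int64)
    return ExpressionMatrix(counts=counts, lengths=lengths, library_sizes=lib)


# ---------------------------------------------------------------------------
# FASTQ read-QC filter
# ---------------------------------------------------------------------------


@dataclass
class QcSummary:
    """Partition of the input reads by the QC filter."""

    total: int = 0
    kept: int = 0
    discarded_n: int = 0
    discarded_quality: int = 0

    @property
    def discarded(self) -> int:
        return self.discarded_n + self.discarded_quality


def filter_fastq(
    in_path: str | os.PathLike,
    out_path: str | os.PathLike,
    cfg: ReadQcConfig | None = None,
) -> QcSummary:
    """Apply the per-read numeric QC filter and write the kept reads.

    A read is discarded iff its N fraction exceeds ``cfg.max_n_fraction`` or
    its fraction of bases at phred <= ``cfg.low_quality_phred`` exceeds
    ``cfg.max_low_quality_fraction``; reads failing both are counted under
    the N reason.  Kept reads are written unchanged.
    """
    from Bio import SeqIO

    cfg = cfg or ReadQcConfig()
    fmt = "fastq" if cfg.phred_offset == 33 else "fastq-illumina"
    summary = QcSummary()

    def _kept(records):
        for rec in records:
            summary.total += 1
            n = len(rec.seq)
            if n == 0:
                summary.kept += 1
                yield rec
                continue
            n_frac = str(rec.seq).upper().count("N") / n
            quals = rec.letter_annotations["phred_quality"]
            lowq_frac = sum(q <= cfg.low_quality_phred for q in quals) / n
            if n_frac > cfg.max_n_fraction:
                summary.discarded_n += 1
            elif lowq_frac > cfg.max_low_quality_fraction:
                summary.discarded_quality += 1
            else:
                summary.kept += 1
                yield rec

    try:
        SeqIO.write(_kept(SeqIO.parse(os.fspath(in_path), fmt)), os.fspath(out_path), fmt)
    except ValueError as exc:
        raise FormatError(f"{in_path}: {exc}") from exc
    return summary
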