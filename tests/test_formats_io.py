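"""I/O boundary behaviour: parsing, round trips, and the read-QC filter."""

import textwrap

import pandas as pd
import pytest

from bsrseq.errors import ConfigError, DuplicateRecordError, FormatError
from bsrseq.formats_io import (
    AlleleCountTable,
    GeneModel,
    ReadQcConfig,
    filter_fastq,
    read_allele_counts,
    read_count_matrix,
    read_gene_models,
    write_gene_models,
)


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(textwrap.dedent(text))
    return path


# ---------------------------------------------------------------------------
# allele-count tables
# ---------------------------------------------------------------------------


class TestAlleleCounts:
    def test_tsv_two_sites_totals_equal_row_sums(self, tmp_path):
        path = _write(
            tmp_path, "counts.tsv",
            """\
            chrom\tpos\tbulk\tcondition\tA\tC\tG\tT
            chr1\t100\ttolerant\tnormal\t12\t0\t8\t0
            chr1\t200\ttolerant\tnormal\t0\t5\t0\t15
            """,
        )
        table = read_allele_counts(path)
        assert table.n_sites == 2
        pooled = table.pooled()
        assert pooled.loc[("chr1", 100)].sum() == 20
        assert pooled.loc[("chr1", 200)].sum() == 20

    def test_negative_count_is_parse_error(self, tmp_path):
        path = _write(
            tmp_path, "bad.tsv",
            """\
            chrom\tpos\tbulk\tcondition\tA\tC\tG\tT
            chr1\t100\ttolerant\tnormal\t-3\t0\t8\t0
            """,
        )
        with pytest.raises(FormatError):
            read_allele_counts(path)

    def test_duplicate_cell_rejected(self, tmp_path):
        path = _write(
            tmp_path, "dup.tsv",
            """\
            chrom\tpos\tbulk\tcondition\tA\tC\tG\tT
            chr1\t100\ttolerant\tnormal\t1\t0\t8\t0
            chr1\t100\ttolerant\tnormal\t2\t0\t8\t0
            """,
        )
        with pytest.raises(DuplicateRecordError):
            read_allele_counts(path)

    def test_missing_cells_filled_with_zero_and_counted(self, tmp_path):
        path = _write(
            tmp_path, "gaps.tsv",
            """\
            chrom\tpos\tbulk\tcondition\tA\tC\tG\tT
            chr1\t100\ttolerant\tnormal\t12\t0\t8\t0
            chr1\t100\tsensitive\tnormal\t2\t0\t18\t0
            chr1\t200\ttolerant\tnormal\t9\t0\t11\t0
            """,
        )
        with pytest.warns(UserWarning, match="missing"):
            table = read_allele_counts(path)
        assert table.load_summary["missing_cells"] == 1
        assert len(table.frame) == 4  # completed grid

    def test_vcf_allelic_depths(self, tmp_path):
        path = _write(
            tmp_path, "sites.vcf",
            """\
            ##fileformat=VCFv4.2
            ##contig=<ID=chr1>
            ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
            ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
            #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ttolerant_normal\tsensitive_normal
            chr1\t100\t.\tA\tG\t.\t.\t.\tGT:AD\t0/1:12,8\t0/0:20,1
            """,
        )
        table = read_allele_counts(path, dialect="vcf")
        frame = table.frame
        cell = frame[(frame.bulk == "tolerant") & (frame.pos == 100)].iloc[0]
        assert (cell.A, cell.G) == (12, 8)
        cell = frame[(frame.bulk == "sensitive") & (frame.pos == 100)].iloc[0]
        assert (cell.A, cell.G) == (20, 1)

    def test_round_trip_exact(self, tmp_path, small_table):
        path = tmp_path / "rt.tsv"
        small_table.to_tsv(path)
        back = read_allele_counts(path)
        pd.testing.assert_frame_equal(back.frame, small_table.frame)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


class TestGeneModels:
    def test_read_preserves_1based_inclusive_span_and_strand(self, tmp_path):
        path = _write(
            tmp_path, "genes.gff3",
            """\
            ##gff-version 3
            chr1\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=geneA
            chr2\tsrc\tgene\t300\t500\t.\t-\t.\tID=geneB
            """,
        )
        genes = read_gene_models(path)
        assert len(genes) == 2
        a = next(g for g in genes if g.gene_id == "geneA")
        assert (a.chrom, a.start, a.end, a.strand) == ("chr1", 1000, 2000, "+")
        b = next(g for g in genes if g.gene_id == "geneB")
        assert b.strand == "-"

    def test_empty_file_yields_empty_set(self, tmp_path):
        path = _write(tmp_path, "empty.gff3", "##gff-version 3\n")
        assert read_gene_models(path) == []

    def test_missing_identifier_is_format_error(self, tmp_path):
        path = _write(
            tmp_path, "noid.gff3",
            "chr1\tsrc\tgene\t1000\t2000\t.\t+\t.\tNote=x\n",
        )
        with pytest.raises(FormatError):
            read_gene_models(path)

    def test_write_read_round_trip(self, tmp_path, gene_models):
        path = tmp_path / "rt.gff3"
        write_gene_models(gene_models, path)
        back = read_gene_models(path)
        assert sorted(back, key=lambda g: g.gene_id) == sorted(
            gene_models, key=lambda g: g.gene_id
        )

    def test_end_before_start_rejected(self):
        with pytest.raises(FormatError):
            GeneModel("bad", "chr1", 2000, 1000)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


class TestCountMatrix:
    def test_library_sizes_default_to_column_sums(self, tmp_path):
        path = _write(
            tmp_path, "counts.tsv",
            """\
            gene_id\tlength\ts1\ts2
            g1\t1000\t10\t20
            g2\t2000\t30\t40
            g3\t500\t0\t5
            """,
        )
        matrix = read_count_matrix(path)
        assert matrix.library_sizes.tolist() == [40, 65]
        assert matrix.lengths.tolist() == [1000, 2000, 500]

    def test_explicit_sidecar_overrides_column_sums(self, tmp_path):
        counts = _write(
            tmp_path, "counts.tsv",
            """\
            gene_id\ts1\ts2
            g1\t10\t20
            """,
        )
        side = _write(
            tmp_path, "libs.tsv",
            """\
            sample\tlibrary_size
            s1\t1000000
            s2\t2000000
            """,
        )
        matrix = read_count_matrix(counts, library_sizes=side)
        assert matrix.library_sizes.tolist() == [1000000, 2000000]

    def test_ragged_row_is_format_error(self, tmp_path):
        path = _write(
            tmp_path, "ragged.tsv",
            """\
            gene_id\ts1\ts2
            g1\t10
            """,
        )
        with pytest.raises(FormatError):
            read_count_matrix(path)

    def test_non_integer_count_is_format_error(self, tmp_path):
        path = _write(
            tmp_path, "frac.tsv",
            """\
            gene_id\ts1\ts2
            g1\t1.5\t2
            """,
        )
        with pytest.raises(FormatError):
            read_count_matrix(path)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        path = _write(
            tmp_path, "dup.tsv",
            """\
            gene_id\ts1
            g1\t1
            g1\t2
            """,
        )
        with pytest.raises(DuplicateRecordError):
            read_count_matrix(path)


# ---------------------------------------------------------------------------
# FASTQ QC filter
# ---------------------------------------------------------------------------


def _fastq_record(name, seq, quals):
    qline = "".join(chr(q + 33) for q in quals)
    return f"@{name}\n{seq}\n+\n{qline}\n"


class TestFilterFastq:
    def _run(self, tmp_path, records, cfg=None):
        src = tmp_path / "in.fastq"
        dst = tmp_path / "out.fastq"
        src.write_text("".join(records))
        summary = filter_fastq(src, dst, cfg)
        return summary, dst

    def test_threshold_boundaries(self, tmp_path):
        ok = _fastq_record("keep", "N" * 5 + "A" * 95, [10] * 20 + [30] * 80)
        too_many_n = _fastq_record("n6", "N" * 6 + "A" * 94, [30] * 100)
        too_low_q = _fastq_record("q21", "A" * 100, [10] * 21 + [30] * 79)
        summary, dst = self._run(tmp_path, [ok, too_many_n, too_low_q])
        assert (summary.total, summary.kept) == (3, 1)
        assert summary.discarded_n == 1 and summary.discarded_quality == 1
        assert "@keep" in dst.read_text()

    def test_partition_and_idempotence(self, tmp_path):
        import random

        rng = random.Random(0)
        records = [
            _fastq_record(
                f"r{i}",
                "".join(rng.choice("ACGTN") for _ in range(50)),
                [rng.randint(2, 40) for _ in range(50)],
            )
            for i in range(60)
        ]
        summary, dst = self._run(tmp_path, records)
        assert summary.kept + summary.discarded == summary.total == 60
        again, _ = self._run(tmp_path, [dst.read_text()])
        assert again.discarded == 0 and again.kept == summary.kept

    def test_length_mismatch_is_format_error(self, tmp_path):
        bad = "@r\nACGT\n+\n!!!\n"
        with pytest.raises(FormatError):
            self._run(tmp_path, [bad])

    def test_kept_reads_written_unchanged(self, tmp_path):
        rec = _fastq_record("r1", "ACGTACGT", [30] * 8)
        _, dst = self._run(tmp_path, [rec])
        assert dst.read_text() == rec


def test_qc_config_validation():
    with pytest.raises(ConfigError):
        ReadQcConfig(max_n_fraction=1.5)
    with pytest.raises(ConfigError):
        ReadQcConfig(low_quality_phred=-1)
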