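"""Per-region read counting: planted counts, oracle equivalence, denominators."""

from __future__ import annotations

import gzip

import numpy as np
import pysam
import pytest

from chipcompart.annotation import GenicRegion
from chipcompart.counting import (
    AlignmentSource,
    CountingOptions,
    build_count_table,
    count_reads_in_region,
    total_sequences,
)
from chipcompart.errors import DataError
from chipcompart.fixtures import FixturePlan, ReadTarget, SamplePlan, make_fixture
from chipcompart.io import SimpleRegion


def write_sam(path, reads, contigs=(("c", 10_000),)):
    """reads: list of (contig, pos1, cigar) or (contig, pos1, cigar, flag)."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": n, "LN": l} for n, l in contigs]}
    ref_index = {n: i for i, (n, _) in enumerate(contigs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as af:
        for i, read in enumerate(sorted(reads, key=lambda r: (r[0], r[1]))):
            contig, pos1, cigar = read[:3]
            flag = read[3] if len(read) > 3 else 0
            seg = pysam.AlignedSegment(af.header)
            seg.query_name = f"r{i}"
            seg.flag = flag
            seg.reference_id = ref_index[contig]
            seg.reference_start = pos1 - 1
            seg.mapping_quality = 60
            seg.cigarstring = cigar
            length = sum(n for op, n in seg.cigartuples if op in (0, 1, 4))
            seg.query_sequence = "A" * length
            af.write(seg)
    return path


def to_bam(sam_path):
    bam_path = sam_path.with_suffix(".bam")
    pysam.sort("-o", str(bam_path), str(sam_path))
    pysam.index(str(bam_path))
    return bam_path


@pytest.fixture(params=["sam", "bam"])
def aligned(request, tmp_path):
    """Factory writing the same alignments as SAM or sorted+indexed BAM."""
    def make(reads, contigs=(("c", 10_000),), role="IP"):
        sam = write_sam(tmp_path / f"{role}.sam", reads, contigs)
        path = to_bam(sam) if request.param == "bam" else sam
        return AlignmentSource(path, role, f"{role.lower()}_sample")
    return make


class TestCountReadsInRegion:
    def test_empty_alignment_counts_zero(self, aligned):
        src = aligned([])
        region = GenicRegion("c", 10, 20, "r")
        assert count_reads_in_region(src, region) == 0

    def test_planted_reads_inside_region(self, aligned):
        reads = [("c", 10, "5M"), ("c", 12, "5M"), ("c", 16, "5M"),
                 ("c", 100, "5M"), ("c", 500, "5M")]
        src = aligned(reads)
        assert count_reads_in_region(src, GenicRegion("c", 10, 20, "r")) == 3

    def test_any_overlap_counts_and_straddler_counts_twice(self, aligned):
        # read spanning 18-27 overlaps both [10,20] and [21,30]
        src = aligned([("c", 18, "10M")])
        left = GenicRegion("c", 10, 20, "left")
        right = GenicRegion("c", 21, 30, "right")
        assert count_reads_in_region(src, left) == 1
        assert count_reads_in_region(src, right) == 1

    def test_soft_clips_do_not_extend_span(self, aligned):
        # aligned span is 30-34; the 5S prefix must not reach back into [20,29]
        src = aligned([("c", 30, "5S5M")])
        assert count_reads_in_region(src, GenicRegion("c", 20, 29, "r")) == 0
        assert count_reads_in_region(src, GenicRegion("c", 30, 39, "r")) == 1

    def test_degenerate_region_counts_zero(self, aligned):
        src = aligned([("c", 10, "10M")])
        region = SimpleRegion("c", 11, 10, "degenerate")
        assert count_reads_in_region(src, region) == 0

    def test_missing_contig_yields_zero_with_single_warning(self, aligned):
        src = aligned([("c", 10, "5M")])
        with pytest.warns(UserWarning, match="absent from alignment header"):
            assert count_reads_in_region(src, GenicRegion("nope", 1, 10, "x")) == 0
            assert count_reads_in_region(src, GenicRegion("nope", 20, 30, "y")) == 0

    def test_unindexed_bam_instructs_to_index(self, tmp_path):
        sam = write_sam(tmp_path / "u.sam", [("c", 10, "5M")])
        bam = tmp_path / "u.bam"
        pysam.sort("-o", str(bam), str(sam))  # sorted but no index
        src = AlignmentSource(bam, "IP", "u")
        with pytest.raises(DataError, match="samtools"):
            count_reads_in_region(src, GenicRegion("c", 1, 100, "r"))

    def test_flag_filters(self, aligned):
        reads = [("c", 10, "5M", 0), ("c", 11, "5M", 256),  # secondary
                 ("c", 12, "5M", 1024), ("c", 13, "5M", 4)]  # duplicate, unmapped
        src = aligned(reads)
        region = GenicRegion("c", 1, 100, "r")
        assert count_reads_in_region(src, region) == 3  # unmapped never counts
        assert count_reads_in_region(
            src, region, CountingOptions(primary_only=True)) == 2
        assert count_reads_in_region(
            src, region, CountingOptions(exclude_duplicates=True)) == 2

    def test_template_unit_counts_distinct_names(self, tmp_path):
        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "c", "LN": 1000}]}
        sam = tmp_path / "t.sam"
        with pysam.AlignmentFile(str(sam), "w", header=header) as af:
            for i, pos in enumerate([10, 15]):
                seg = pysam.AlignedSegment(af.header)
                seg.query_name = "same_template"
                seg.reference_id = 0
                seg.reference_start = pos
                seg.mapping_quality = 60
                seg.cigarstring = "5M"
                seg.query_sequence = "AAAAA"
                af.write(seg)
        src = AlignmentSource(sam, "IP", "t")
        region = GenicRegion("c", 1, 100, "r")
        assert count_reads_in_region(src, region, CountingOptions()) == 2
        assert count_reads_in_region(
            src, region, CountingOptions(count_unit="template")) == 1


class TestOracleEquivalence:
    def test_random_reads_vs_brute_force(self, tmp_path):
        """1,000 random reads x 60 random regions against an all-pairs scan."""
        rng = np.random.default_rng(2024)
        contig_len = 50_000
        read_len = 66
        starts = rng.integers(1, contig_len - read_len + 1, size=1000)
        reads = [("c", int(s), f"{read_len}M") for s in starts]
        sam = write_sam(tmp_path / "rand.sam", reads, (("c", contig_len),))
        bam = to_bam(sam)

        regions = []
        for i in range(60):
            s = int(rng.integers(1, contig_len))
            e = min(contig_len, s + int(rng.integers(0, 2000)))
            regions.append(GenicRegion("c", s, e, f"reg{i}"))

        read_iv = [(s, s + read_len - 1) for s in starts]
        expected = [
            sum(1 for rs, re in read_iv if rs <= r.end and re >= r.start)
            for r in regions
        ]
        for source in (AlignmentSource(sam, "IP", "s"),
                       AlignmentSource(bam, "IP", "s")):
            got = [count_reads_in_region(source, r) for r in regions]
            assert got == expected


class TestBuildCountTable:
    def test_planted_pair_counts(self, tmp_path):
        input_sam = write_sam(tmp_path / "in.sam",
                              [("c", 10, "5M")] * 5)
        ip_sam = write_sam(tmp_path / "ip.sam",
                           [("c", 10, "5M")] * 10 + [("c", 200, "5M")] * 4)
        regions = [GenicRegion("c", 1, 100, "a"), GenicRegion("c", 150, 300, "b")]
        table = build_count_table(
            AlignmentSource(input_sam, "INPUT", "in"),
            AlignmentSource(ip_sam, "IP", "ip"),
            regions,
        )
        assert table["input_count"].tolist() == [5, 0]
        assert table["ip_count"].tolist() == [10, 4]
        assert table["region_id"].tolist() == ["a", "b"]

    @pytest.mark.parametrize("workers", [2, 4])
    def test_parallel_equals_serial(self, tmp_path, workers):
        rng = np.random.default_rng(5)
        reads = [("c", int(s), "66M") for s in rng.integers(1, 9000, size=300)]
        input_bam = to_bam(write_sam(tmp_path / "in.sam", reads))
        ip_bam = to_bam(write_sam(tmp_path / "ip.sam", reads[::2]))
        regions = [GenicRegion("c", 1 + 200 * i, 200 + 200 * i, f"r{i}")
                   for i in range(40)]
        src_in = AlignmentSource(input_bam, "INPUT", "in")
        src_ip = AlignmentSource(ip_bam, "IP", "ip")
        serial = build_count_table(src_in, src_ip, regions, workers=1)
        parallel = build_count_table(src_in, src_ip, regions, workers=workers)
        assert parallel.equals(serial)

    def test_reference_mismatch_warns(self, tmp_path):
        input_sam = write_sam(tmp_path / "in.sam", [], (("c", 100),))
        ip_sam = write_sam(tmp_path / "ip.sam", [], (("c", 100), ("d", 100)))
        with pytest.warns(UserWarning, match="reference name mismatch"):
            build_count_table(
                AlignmentSource(input_sam, "INPUT", "in"),
                AlignmentSource(ip_sam, "IP", "ip"),
                [GenicRegion("c", 1, 50, "r")],
            )

    def test_empty_region_list_rejected(self, tmp_path):
        sam = write_sam(tmp_path / "in.sam", [])
        src = AlignmentSource(sam, "INPUT", "in")
        with pytest.raises(DataError, match="empty region"):
            build_count_table(src, src, [])

    def test_fixture_counts_equal_recorded_truth(self, minimal_fixture):
        fx = minimal_fixture
        regions = [
            GenicRegion(r.contig, r.start, r.end, r.label)
            for r in fx.truth[fx.truth.sample_id == "tag_input"].itertuples()
        ]
        table = build_count_table(
            AlignmentSource(fx.bams["tag_input"], "INPUT", "tag_input"),
            AlignmentSource(fx.bams["tag_ip"], "IP", "tag_ip"),
            regions,
        )
        truth_in = fx.truth[fx.truth.sample_id == "tag_input"].set_index("label")
        truth_ip = fx.truth[fx.truth.sample_id == "tag_ip"].set_index("label")
        for row in table.itertuples():
            assert row.input_count == truth_in.loc[row.region_id, "emitted"]
            assert row.ip_count == truth_ip.loc[row.region_id, "emitted"]


class TestTotalSequences:
    def test_fastq_record_count(self, tmp_path):
        fq = tmp_path / "r.fastq"
        fq.write_text("".join(f"@r{i}\nACGT\n+\nIIII\n" for i in range(8)))
        assert total_sequences(fq) == 8

    def test_gzip_transparency(self, tmp_path):
        fq = tmp_path / "r.fastq.gz"
        with gzip.open(fq, "wt") as fh:
            fh.write("".join(f"@r{i}\nACGT\n+\nIIII\n" for i in range(8)))
        assert total_sequences(fq) == 8

    def test_truncated_fastq_reports_record_index(self, tmp_path):
        fq = tmp_path / "bad.fastq"
        fq.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\n")
        with pytest.raises(DataError, match="index 1"):
            total_sequences(fq)

    def test_alignment_denominator_is_primary_mapped_only(self, tmp_path):
        reads = ([("c", 10, "5M", 0)] * 10 + [("c", 20, "5M", 256)] * 2
                 + [("c", 30, "5M", 4)])
        sam = write_sam(tmp_path / "a.sam", reads)
        bam = to_bam(sam)
        assert total_sequences(bam) == 10
        assert total_sequences(AlignmentSource(sam, "INPUT", "a")) == 10
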