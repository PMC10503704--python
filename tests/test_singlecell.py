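import numpy as np
import pytest

from splicetracks.coverage import compute_track
from splicetracks.regions import ExonBlock, GenomicRegion
from splicetracks.simulate import ReadSpec, make_reads, write_bam, write_barcode_table
from splicetracks.singlecell import (
    demultiplex,
    read_barcode_table,
    strand_split,
    transcribed_strand,
)

REGION = GenomicRegion("chr1", 10_000, 10_200)


def block(start=10_000, end=10_100):
    return [ExonBlock(start, end)]


class TestBarcodeTable:
    def test_three_rows_two_groups(self, tmp_path):
        path = write_barcode_table(
            {"AAA": "T", "CCC": "T", "GGG": "B"}, tmp_path / "bc.tsv"
        )
        table = read_barcode_table(path)
        assert len(table) == 3
        assert table.group_labels() == ["T", "B"]

    def test_duplicate_same_group_counted_once(self, tmp_path):
        path = tmp_path / "bc.tsv"
        path.write_text("AAA\tT\nAAA\tT\nCCC\tB\n")
        assert len(read_barcode_table(path)) == 2

    def test_conflicting_groups_error_names_barcode(self, tmp_path):
        path = tmp_path / "bc.tsv"
        path.write_text("AAA\tT\nAAA\tB\n")
        with pytest.raises(ValueError, match="AAA"):
            read_barcode_table(path)

    def test_csv_with_header_accepted(self, tmp_path):
        path = tmp_path / "bc.csv"
        path.write_text("barcode,group\nAAA,T\nCCC,B\n")
        assert len(read_barcode_table(path)) == 2


class TestDemultiplex:
    def table(self, tmp_path, groups=None):
        path = write_barcode_table(groups or {"AAA": "T", "CCC": "B"},
                                   tmp_path / "bc.tsv")
        return read_barcode_table(path)

    def test_same_umi_same_position_collapses(self, tmp_path):
        reads = [
            ReadSpec("r1", block(), tags={"CB": "AAA", "UB": "U1"}),
            ReadSpec("r2", block(), tags={"CB": "AAA", "UB": "U1"}),
        ]
        bam = write_bam(reads, tmp_path / "a.bam")
        tracks, stats = demultiplex(bam, REGION, self.table(tmp_path))
        assert tracks["T"].depth.max() == 1
        assert stats.duplicate_collapsed == 1 and stats.used == 1

    def test_distinct_umis_both_count(self, tmp_path):
        reads = [
            ReadSpec("r1", block(), tags={"CB": "AAA", "UB": "U1"}),
            ReadSpec("r2", block(), tags={"CB": "AAA", "UB": "U2"}),
        ]
        bam = write_bam(reads, tmp_path / "a.bam")
        tracks, _ = demultiplex(bam, REGION, self.table(tmp_path))
        assert tracks["T"].depth.max() == 2

    def test_recycled_umi_at_new_position_survives_by_default(self, tmp_path):
        reads = [
            ReadSpec("r1", block(10_000, 10_100), tags={"CB": "AAA", "UB": "U1"}),
            ReadSpec("r2", block(10_050, 10_150), tags={"CB": "AAA", "UB": "U1"}),
        ]
        bam = write_bam(reads, tmp_path / "a.bam")
        tracks, _ = demultiplex(bam, REGION, self.table(tmp_path))
        assert tracks["T"].depth.max() == 2
        # position-free key collapses them
        tracks2, _ = demultiplex(bam, REGION, self.table(tmp_path),
                                 dedup_on_position=False)
        assert tracks2["T"].depth.max() == 1

    def test_unlisted_barcode_excluded_everywhere(self, tmp_path):
        reads = [ReadSpec("r1", block(), tags={"CB": "TTT", "UB": "U1"})]
        bam = write_bam(reads, tmp_path / "a.bam")
        tracks, stats = demultiplex(bam, REGION, self.table(tmp_path))
        assert all(not t.depth.any() for t in tracks.values())
        assert stats.dropped_barcode == 1

    def test_every_group_gets_a_track_even_if_empty(self, tmp_path):
        reads = [ReadSpec("r1", block(), tags={"CB": "AAA", "UB": "U1"})]
        bam = write_bam(reads, tmp_path / "a.bam")
        tracks, _ = demultiplex(bam, REGION, self.table(tmp_path))
        assert set(tracks) == {"T", "B"}
        assert not tracks["B"].depth.any()

    def test_missing_umi_kept_without_dedup(self, tmp_path):
        reads = [
            ReadSpec("r1", block(), tags={"CB": "AAA"}),
            ReadSpec("r2", block(), tags={"CB": "AAA"}),
        ]
        bam = write_bam(reads, tmp_path / "a.bam")
        tracks, stats = demultiplex(bam, REGION, self.table(tmp_path))
        assert tracks["T"].depth.max() == 2
        assert stats.missing_umi == 2

    def test_conservation_accounting(self, tmp_path, gene):
        barcodes = ["AAA", "CCC", "TTT"]  # TTT is unlisted
        fx = make_reads(gene.transcript, tmp_path / "sc.bam",
                        n_inclusion=30, n_exclusion=20,
                        barcodes=barcodes,
                        umis=[f"U{i}" for i in range(8)], seed=5)
        region = GenomicRegion("chr1", gene.transcript.start,
                               gene.transcript.end)
        tracks, stats = demultiplex(fx.bam_path, region, self.table(tmp_path))
        assert stats.total_passing == fx.manifest["n_reads"]
        assert stats.used == sum(stats.per_group_used.values())

    def test_group_sum_equals_whole_file_dedup_depth(self, tmp_path, gene):
        # oracle: single-pass brute force over listed barcodes
        fx = make_reads(gene.transcript, tmp_path / "sc.bam",
                        n_inclusion=30, n_exclusion=20,
                        barcodes=["AAA", "CCC"],
                        umis=[f"U{i}" for i in range(7)], seed=6)
        region = GenomicRegion("chr1", gene.transcript.start,
                               gene.transcript.end)
        tracks, _ = demultiplex(fx.bam_path, region, self.table(tmp_path))
        combined = sum(t.depth for t in tracks.values())

        seen, expected = set(), np.zeros(region.length())
        # iterate in BAM record order (stable coordinate sort) so the
        # surviving read of each dedup key matches the engine's
        for spec in sorted(fx.reads, key=lambda r: r.start):
            key = (spec.tags["CB"], spec.tags["UB"], spec.start)
            if spec.tags["CB"] not in ("AAA", "CCC") or key in seen:
                continue
            seen.add(key)
            for b in spec.blocks:
                lo = max(b.start, region.start) - region.start
                hi = min(b.end, region.end) - region.start
                expected[lo:hi] += 1
        assert np.array_equal(combined, expected)

    def test_dedup_idempotent(self, tmp_path, gene):
        fx = make_reads(gene.transcript, tmp_path / "sc.bam",
                        n_inclusion=30, n_exclusion=20,
                        barcodes=["AAA", "CCC"],
                        umis=[f"U{i}" for i in range(5)], seed=7)
        region = GenomicRegion("chr1", gene.transcript.start,
                               gene.transcript.end)
        tracks1, stats1 = demultiplex(fx.bam_path, region, self.table(tmp_path))
        # rewrite only the deduplicated reads, demultiplex again
        seen, survivors = set(), []
        for spec in sorted(fx.reads, key=lambda r: r.start):
            if spec.tags["CB"] not in ("AAA", "CCC"):
                continue
            key = (spec.tags["CB"], spec.tags["UB"], spec.start)
            if key not in seen:
                seen.add(key)
                survivors.append(spec)
        bam2 = write_bam(survivors, tmp_path / "dedup.bam")
        tracks2, stats2 = demultiplex(bam2, region, self.table(tmp_path))
        assert stats2.duplicate_collapsed == 0
        for g in tracks1:
            assert np.array_equal(tracks1[g].depth, tracks2[g].depth)
            assert tracks1[g].junctions == tracks2[g].junctions


class TestStrandSplit:
    @pytest.mark.parametrize(
        "is_reverse, strandness, expected",
        [
            (False, "forward", "+"),   # + flag, forward library -> sense
            (False, "reverse", "-"),   # + flag, reverse library -> antisense
            (True, "forward", "-"),
            (True, "reverse", "+"),
        ],
    )
    def test_transcribed_strand_rules(self, is_reverse, strandness, expected):
        assert transcribed_strand(is_reverse, strandness) == expected

    def test_forward_library_split(self, tmp_path):
        reads = [
            ReadSpec("f", block(), is_reverse=False),
            ReadSpec("r", block(), is_reverse=True),
        ]
        bam = write_bam(reads, tmp_path / "a.bam")
        sense, anti = strand_split(bam, REGION, "forward")
        assert sense.depth.max() == 1 and anti.depth.max() == 1

    def test_reverse_library_inverts(self, tmp_path):
        reads = [ReadSpec("f", block(), is_reverse=False)]
        bam = write_bam(reads, tmp_path / "a.bam")
        sense, anti = strand_split(bam, REGION, "reverse")
        assert not sense.depth.any() and anti.depth.max() == 1

    def test_unstranded_puts_everything_in_sense(self, tmp_path):
        reads = [
            ReadSpec("f", block(), is_reverse=False),
            ReadSpec("r", block(), is_reverse=True),
        ]
        bam = write_bam(reads, tmp_path / "a.bam")
        sense, anti = strand_split(bam, REGION, "unstranded")
        assert sense.depth.max() == 2
        assert not anti.depth.any()
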