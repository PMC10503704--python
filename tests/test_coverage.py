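import re

import numpy as np
import pysam
import pytest

from splicetracks.coverage import (
    CoverageTrack,
    MalformedCigarError,
    aggregate_tracks,
    compute_psi,
    compute_track,
    normalize_track,
    segment_blocks,
)
from splicetracks.regions import ExonBlock, GenomicRegion, Junction, parse_region
from splicetracks.simulate import ReadSpec, make_random_reads, make_reads, write_bam


def cigar_walk_oracle(pos, cigar):
    """Independent CIGAR interpreter: expand to per-base reference positions,
    then regroup into blocks and gaps."""
    ref_positions, gaps = [], []
    cursor = pos
    for length, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        length = int(length)
        if op in "MDX=":
            ref_positions.extend(range(cursor, cursor + length))
            cursor += length
        elif op == "N":
            gaps.append((cursor, cursor + length))
            cursor += length
    blocks = []
    for p in ref_positions:
        if blocks and p == blocks[-1][1]:
            blocks[-1][1] = p + 1
        else:
            blocks.append([p, p + 1])
    return [tuple(b) for b in blocks], gaps


def seg_from(pos, cigar, tmp_path):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 10**6}]}
    )
    seg = pysam.AlignedSegment(header)
    seg.query_name = "r"
    seg.reference_id = 0
    seg.reference_start = pos
    seg.cigarstring = cigar
    qlen = sum(int(n) for n, op in re.findall(r"(\d+)([MIS=X])", cigar))
    seg.query_sequence = "A" * qlen
    return seg


class TestSegmentBlocks:
    @pytest.mark.parametrize(
        "pos, cigar",
        [
            (1000, "50M100N50M"),
            (1000, "100M"),
            (1000, "10M5D10M"),
            (1000, "5S20M300N30M2I10M4S"),
            (1000, "10M1N10M1N10M"),
        ],
    )
    def test_matches_per_base_oracle(self, pos, cigar, tmp_path):
        blocks, junctions = segment_blocks(seg_from(pos, cigar, tmp_path))
        exp_blocks, exp_gaps = cigar_walk_oracle(pos, cigar)
        assert [(b.start, b.end) for b in blocks] == exp_blocks
        assert [(j.donor, j.acceptor) for j in junctions] == exp_gaps

    def test_spliced_read_example(self, tmp_path):
        blocks, junctions = segment_blocks(seg_from(1000, "50M100N50M", tmp_path))
        assert [(b.start, b.end) for b in blocks] == [(1000, 1050), (1150, 1200)]
        assert [(j.donor, j.acceptor) for j in junctions] == [(1050, 1150)]

    def test_deletion_does_not_split_block(self, tmp_path):
        blocks, junctions = segment_blocks(seg_from(1000, "10M5D10M", tmp_path))
        assert [(b.start, b.end) for b in blocks] == [(1000, 1025)]
        assert junctions == []

    @pytest.mark.parametrize("cigar", ["100N50M", "50M100N", "10N10M10N"])
    def test_leading_or_trailing_gap_is_malformed(self, cigar, tmp_path):
        with pytest.raises(MalformedCigarError):
            segment_blocks(seg_from(1000, cigar, tmp_path))


class TestComputeTrack:
    def test_identical_reads_give_constant_depth(self, tmp_path):
        reads = [ReadSpec(f"r{i}", [ExonBlock(10_000, 10_100)]) for i in range(3)]
        bam = write_bam(reads, tmp_path / "a.bam")
        track = compute_track(bam, GenomicRegion("chr1", 10_000, 10_100))
        assert (track.depth == 3).all()
        assert track.junctions == {}
        assert track.library_size == 3

    def test_junction_counts_by_construction(self, tmp_path, gene):
        # 7 reads over exon1-exon2, 3 over exon1-exon3 (skipping)
        e1, e2, e3 = gene.transcript.exons
        reads = [
            ReadSpec(f"i{k}", [ExonBlock(e1.end - 50, e1.end),
                               ExonBlock(e2.start, e2.start + 50)])
            for k in range(7)
        ] + [
            ReadSpec(f"s{k}", [ExonBlock(e1.end - 50, e1.end),
                               ExonBlock(e3.start, e3.start + 50)])
            for k in range(3)
        ]
        bam = write_bam(reads, tmp_path / "a.bam")
        track = compute_track(bam, GenomicRegion("chr1", 9_900, 10_800))
        assert track.junctions == {
            Junction(e1.end, e2.start): 7,
            Junction(e1.end, e3.start): 3,
        }

    def test_empty_window_is_all_zero(self, tmp_path):
        bam = write_bam([ReadSpec("r", [ExonBlock(10_000, 10_100)])],
                        tmp_path / "a.bam")
        track = compute_track(bam, GenomicRegion("chr1", 500_000, 500_100))
        assert not track.depth.any()
        assert track.junctions == {}

    def test_missing_index_instructs_to_index(self, tmp_path):
        bam = write_bam([ReadSpec("r", [ExonBlock(10_000, 10_100)])],
                        tmp_path / "a.bam")
        bam.with_suffix(".bam.bai").unlink()
        with pytest.raises(FileNotFoundError, match="index"):
            compute_track(bam, GenomicRegion("chr1", 10_000, 10_100))

    def test_unknown_chromosome_after_alias_pass(self, tmp_path):
        bam = write_bam([ReadSpec("r", [ExonBlock(10_000, 10_100)])],
                        tmp_path / "a.bam")
        with pytest.raises(ValueError, match="chr9"):
            compute_track(bam, GenomicRegion("chr9", 10_000, 10_100))

    def test_alias_pass_matches_unprefixed_header(self, tmp_path):
        bam = write_bam([ReadSpec("r", [ExonBlock(10_000, 10_100)])],
                        tmp_path / "a.bam", chrom="1")
        track = compute_track(bam, GenomicRegion("chr1", 10_000, 10_100))
        assert (track.depth == 1).all()

    def test_depth_sum_matches_per_read_rasterizer(self, tmp_path):
        fx = make_random_reads(tmp_path / "r.bam", n_reads=80, seed=11)
        region = parse_region(fx.manifest["region"])
        track = compute_track(fx.bam_path, region)
        # brute force: per-read overlap of construction blocks with window
        expected = sum(
            max(0, min(b.end, region.end) - max(b.start, region.start))
            for r in fx.reads
            for b in r.blocks
        )
        assert track.depth.sum() == expected

    def test_read_order_invariance(self, tmp_path, gene):
        fxs = [
            make_reads(gene.transcript, tmp_path / f"{i}.bam",
                       n_inclusion=20, n_exclusion=10, seed=i)
            for i in (1, 2)  # same reads, different shuffle
        ]
        region = parse_region(fxs[0].manifest["region"])
        t1 = compute_track(fxs[0].bam_path, region)
        t2 = compute_track(fxs[1].bam_path, region)
        assert t1.junctions == t2.junctions
        assert np.array_equal(t1.depth, t2.depth)


class TestNormalize:
    def make_track(self, depth, library_size, length=None):
        length = length or len(depth)
        region = GenomicRegion("chr1", 0, length)
        return CoverageTrack(region, np.asarray(depth, float),
                             library_size=library_size)

    def test_rpm_scaling(self):
        track = self.make_track([10.0, 4.0], 2_000_000)
        rpm = normalize_track(track, "rpm")
        assert rpm.depth.tolist() == [5.0, 2.0]
        assert rpm.units == "rpm"

    def test_rpkm_formula(self):
        region = GenomicRegion("chr1", 0, 1000)
        track = CoverageTrack(region, np.full(1000, 10.0), library_size=1_000_000)
        rpkm = normalize_track(track, "rpkm")
        assert rpkm.depth[0] == pytest.approx(10.0)  # 10 * 1e9 / (1e6 * 1e3)

    def test_raw_is_identity(self):
        track = self.make_track([1.0, 2.0], 100)
        assert normalize_track(track, "raw") is track

    def test_zero_library_rejected(self):
        track = self.make_track([1.0], 0)
        with pytest.raises(ValueError, match="library_size"):
            normalize_track(track, "rpm")

    def test_rpm_preserves_depth_ratios(self):
        track = self.make_track([3.0, 12.0, 7.0], 5_000_000)
        rpm = normalize_track(track, "rpm")
        nz = track.depth > 0
        assert np.allclose(rpm.depth[nz] / rpm.depth[0], track.depth[nz] / track.depth[0])

    def test_junction_counts_stay_raw(self):
        region = GenomicRegion("chr1", 0, 100)
        track = CoverageTrack(region, np.ones(100), {Junction(10, 20): 7},
                              library_size=10**6)
        assert normalize_track(track, "rpm").junctions == {Junction(10, 20): 7}


class TestAggregate:
    def make(self, depth, junctions=None):
        region = GenomicRegion("chr1", 0, len(depth))
        return CoverageTrack(region, np.asarray(depth, float), junctions or {},
                             library_size=100)

    def test_mean(self):
        out = aggregate_tracks([self.make([2, 4]), self.make([4, 8])], "mean")
        assert out.depth.tolist() == [3.0, 6.0]

    def test_single_track_sum_is_identity(self):
        t = self.make([1, 2, 3])
        out = aggregate_tracks([t], "sum")
        assert np.array_equal(out.depth, t.depth)

    def test_junction_union_with_absent_as_zero(self):
        j = Junction(10, 20)
        zeros = [0] * 30
        out = aggregate_tracks(
            [self.make([1] * 30, {j: 3}), self.make(zeros)], "sum"
        )
        assert out.junctions == {j: 3}

    def test_mean_junction_rounds_half_up(self):
        j = Junction(10, 20)
        zeros = [0] * 30
        out = aggregate_tracks(
            [self.make(zeros, {j: 3}), self.make(zeros, {j: 4})], "mean"
        )
        assert out.junctions == {j: 4}  # 3.5 rounds half-up

    def test_region_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            aggregate_tracks([self.make([1]), self.make([1, 2])], "mean")


class TestPsi:
    def brute_force_psi(self, junctions, exon):
        inc = sum(c for j, c in junctions.items()
                  if j.acceptor == exon.start or j.donor == exon.end)
        exc = sum(c for j, c in junctions.items()
                  if j.donor <= exon.start and j.acceptor >= exon.end)
        return inc / (inc + exc) if inc + exc else None

    def test_mixed_inclusion_exclusion(self):
        exon = ExonBlock(300, 400)
        junctions = {
            Junction(200, 300): 30,  # upstream inclusion
            Junction(400, 500): 30,  # downstream inclusion
            Junction(200, 500): 40,  # spanning exclusion
        }
        psi = compute_psi(junctions, exon)
        assert psi.value == pytest.approx(0.6)
        assert psi.inclusion_count == 60 and psi.exclusion_count == 40
        assert psi.value == pytest.approx(self.brute_force_psi(junctions, exon))

    def test_constitutive_exon_is_one(self):
        psi = compute_psi({Junction(200, 300): 5}, ExonBlock(300, 400))
        assert psi.value == 1.0

    def test_empty_map_is_undefined(self):
        psi = compute_psi({}, ExonBlock(300, 400))
        assert psi.value is None and not psi.defined
        assert f"{psi}" == "NA"

    def test_bounded_on_random_junction_sets(self):
        rng = np.random.default_rng(7)
        exon = ExonBlock(1000, 1100)
        for _ in range(50):
            junctions = {}
            for _ in range(rng.integers(1, 10)):
                a = int(rng.integers(500, 1500))
                b = int(rng.integers(a + 1, 2000))
                junctions[Junction(a, b)] = int(rng.integers(1, 30))
            psi = compute_psi(junctions, exon)
            if psi.defined:
                assert 0.0 <= psi.value <= 1.0
            assert psi.value == pytest.approx(
                self.brute_force_psi(junctions, exon)
            ) or psi.value is None
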