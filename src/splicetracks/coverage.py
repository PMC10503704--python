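"""Alignment-file engine: per-base depth, junction counts, normalization,
aggregation, and percent-spliced-in (PSI).

Splice junctions are recovered from the N operations of each read's CIGAR
("all splicing reads including novel junctions" semantics): no annotation is
consulted, so unannotated junctions are counted exactly like known ones.

PSI for a target exon is the junction-read estimator

    psi = inclusion / (inclusion + exclusion)

where *inclusion* counts junction reads landing on either flank of the exon
(a read supporting both flanks is counted on both, matching standard
junction-PSI practice) and *exclusion* counts junction reads splicing
completely over the exon.  With no informative junctions at all the value is
flagged undefined rather than raised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

from .regions import ExonBlock, GenomicRegion, Junction, resolve_chrom

log = logging.getLogger(__name__)

__all__ = [
    "ReadFilters",
    "CoverageTrack",
    "PsiValue",
    "MalformedCigarError",
    "segment_blocks",
    "compute_track",
    "normalize_track",
    "aggregate_tracks",
    "compute_psi",
]

# pysam CIGAR op codes
_M, _I, _D, _N, _S, _H, _P, _EQ, _X = 0, 1, 2, 3, 4, 5, 6, 7, 8
_REF_CONSUMING = {_M, _D, _N, _EQ, _X}
_BLOCK_OPS = {_M, _D, _EQ, _X}


class MalformedCigarError(ValueError):
    """CIGAR whose reference walk starts or ends with an N operation."""


@dataclass
class ReadFilters:
    """Read-level filters applied by every extraction routine.

    Defaults keep everything: mapq 0, duplicate-flagged reads retained
    (bulk pipelines usually mark duplicates intentionally), secondary and
    supplementary alignments dropped.  The single-cell path overrides
    ``drop_duplicates``.
    """

    min_mapq: int = 0
    drop_duplicates: bool = False
    strand: str = "."  # required read strand; "." = pass-all
    barcode_whitelist: frozenset[str] | None = None
    barcode_tag: str = "CB"
    exclude_secondary: bool = True

    def passes(self, seg: pysam.AlignedSegment) -> bool:
        if seg.is_unmapped or seg.mapping_quality < self.min_mapq:
            return False
        if self.exclude_secondary and (seg.is_secondary or seg.is_supplementary):
            return False
        if self.drop_duplicates and seg.is_duplicate:
            return False
        if self.strand != "." and read_strand(seg) != self.strand:
            return False
        if self.barcode_whitelist is not None:
            if not seg.has_tag(self.barcode_tag):
                return False
            if seg.get_tag(self.barcode_tag) not in self.barcode_whitelist:
                return False
        return True


def read_strand(seg: pysam.AlignedSegment) -> str:
    return "-" if seg.is_reverse else "+"


def junction_strand(seg: pysam.AlignedSegment) -> str:
    """Strand assigned to a junction: XS/ts tag when present, else '.'."""
    for tag in ("XS", "ts"):
        if seg.has_tag(tag):
            v = seg.get_tag(tag)
            if v in ("+", "-"):
                return v
    return "."


@dataclass
class PsiValue:
    """Percent-spliced-in with its supporting junction-read counts."""

    value: float | None
    inclusion_count: int
    exclusion_count: int

    @property
    def defined(self) -> bool:
        return self.value is not None

    def __format__(self, spec: str) -> str:
        return "NA" if self.value is None else format(self.value, spec or ".3f")


@dataclass
class CoverageTrack:
    """Per-base depth plus junction counts over one region for one sample/group.

    ``depth`` has exactly ``region.length()`` entries (index i is genomic
    position ``region.start + i``); ``junctions`` maps each intron interval
    to the number of supporting reads.  ``library_size`` is the total mapped
    reads of the source file so that RPM/RPKM are window-independent.
    """

    region: GenomicRegion
    depth: np.ndarray
    junctions: dict[Junction, float] = field(default_factory=dict)
    label: str = ""
    color: str = "#377eb8"
    library_size: int = 0
    units: str = "reads"

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (self.region.length(),):
            raise ValueError(
                f"depth length {self.depth.shape} != region length {self.region.length()}"
            )
        if (self.depth < 0).any():
            raise ValueError("negative depth values")
        for j in self.junctions:
            if not self.region.overlaps(j.donor, j.acceptor):
                raise ValueError(f"junction {j} outside region {self.region}")


def segment_blocks(seg: pysam.AlignedSegment) -> tuple[list[ExonBlock], list[Junction]]:
    """Walk a read's CIGAR into aligned blocks and splice junctions.

    M/=/X/D consume reference into the current block (a deletion does not
    split it); N closes the block and emits the intron as a Junction;
    I/S/H/P consume no reference.  A CIGAR whose reference-consuming walk
    begins or ends with N is malformed and raises
    :class:`MalformedCigarError` (callers skip and count such reads).
    """
    cig = seg.cigartuples
    if not cig:
        return [], []
    ref_ops = [op for op, _ in cig if op in _REF_CONSUMING]
    if ref_ops and (ref_ops[0] == _N or ref_ops[-1] == _N):
        raise MalformedCigarError(f"{seg.query_name}: CIGAR starts/ends with N")
    strand = junction_strand(seg)
    blocks: list[ExonBlock] = []
    junctions: list[Junction] = []
    pos = seg.reference_start
    block_start = pos
    for op, length in cig:
        if op in _BLOCK_OPS:
            pos += length
        elif op == _N:
            if pos > block_start:
                blocks.append(ExonBlock(block_start, pos))
            junctions.append(Junction(pos, pos + length, strand))
            pos += length
            block_start = pos
    if pos > block_start:
        blocks.append(ExonBlock(block_start, pos))
    return blocks, junctions


def _open_bam(bam_path, region: GenomicRegion) -> tuple[pysam.AlignmentFile, str]:
    bam = pysam.AlignmentFile(str(bam_path))
    if not bam.has_index():
        bam.close()
        raise FileNotFoundError(
            f"{bam_path} has no index; run `samtools index` first"
        )
    chrom = resolve_chrom(region.chrom, bam.references)
    if chrom is None:
        bam.close()
        raise ValueError(
            f"chromosome {region.chrom!r} absent from {bam_path} header "
            f"(also tried chr-prefix alias)"
        )
    return bam, chrom


def mapped_read_count(bam: pysam.AlignmentFile) -> int:
    """Total mapped reads from the index statistics (whole file, not window)."""
    return sum(s.mapped for s in bam.get_index_statistics())


def rasterize(blocks: list[ExonBlock], region: GenomicRegion, depth: np.ndarray) -> None:
    """Add one read's block coverage into ``depth`` (in place)."""
    for b in blocks:
        lo = max(b.start, region.start) - region.start
        hi = min(b.end, region.end) - region.start
        if hi > lo:
            depth[lo:hi] += 1


def compute_track(
    bam_path,
    region: GenomicRegion,
    filters: ReadFilters | None = None,
    label: str = "",
    color: str = "#377eb8",
) -> CoverageTrack:
    """Extract a :class:`CoverageTrack` from a coordinate-sorted indexed BAM.

    ``depth[i]`` counts passing reads whose aligned blocks cover position
    ``region.start + i``; junction counts are restricted to junctions
    overlapping the region.  Reads with malformed CIGARs are skipped and
    logged.
    """
    filters = filters or ReadFilters()
    depth = np.zeros(region.length(), dtype=float)
    junctions: dict[Junction, float] = {}
    malformed = 0
    bam, chrom = _open_bam(bam_path, region)
    with bam:
        library_size = mapped_read_count(bam)
        for seg in bam.fetch(chrom, region.start, region.end):
            if not filters.passes(seg):
                continue
            try:
                blocks, juncs = segment_blocks(seg)
            except MalformedCigarError:
                malformed += 1
                continue
            rasterize(blocks, region, depth)
            for j in juncs:
                if region.overlaps(j.donor, j.acceptor):
                    junctions[j] = junctions.get(j, 0) + 1
    if malformed:
        log.warning("%s: skipped %d reads with malformed CIGARs", bam_path, malformed)
    return CoverageTrack(
        region, depth, junctions, label=label or str(bam_path), color=color,
        library_size=library_size,
    )


def normalize_track(track: CoverageTrack, method: str = "raw") -> CoverageTrack:
    """Return a new track with depth scaled to raw / RPM / RPKM units.

    rpm  = depth * 1e6 / library_size
    rpkm = depth * 1e9 / (library_size * region_length_bp)

    Junction counts stay raw integers in every mode.
    """
    if method == "raw":
        return track
    if method not in ("rpm", "rpkm"):
        raise ValueError(f"unknown normalization {method!r}")
    if track.library_size <= 0:
        raise ValueError(f"library_size must be > 0 for {method} normalization")
    scale = 1e6 / track.library_size
    if method == "rpkm":
        scale = 1e9 / (track.library_size * track.region.length())
    return replace(track, depth=track.depth * scale, units=method)


def aggregate_tracks(tracks: list[CoverageTrack], mode: str = "mean") -> CoverageTrack:
    """Combine same-region tracks element-wise by ``mean`` or ``sum``.

    Junction counts are combined the same way over the union of junctions
    (absent = 0); a mean junction count is rounded half-up to an int for
    display.
    """
    if not tracks:
        raise ValueError("need at least one track")
    if mode not in ("mean", "sum"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    region = tracks[0].region
    for t in tracks[1:]:
        if t.region != region:
            raise ValueError(f"region mismatch: {t.region} != {region}")
    depth = np.sum([t.depth for t in tracks], axis=0)
    keys = set()
    for t in tracks:
        keys.update(t.junctions)
    junctions = {k: float(sum(t.junctions.get(k, 0) for t in tracks)) for k in keys}
    if mode == "mean":
        n = len(tracks)
        depth = depth / n
        junctions = {k: float(int(v / n + 0.5)) for k, v in junctions.items()}
    lib = sum(t.library_size for t in tracks)
    if mode == "mean":
        lib = int(lib / len(tracks) + 0.5)
    return CoverageTrack(
        region, depth, junctions,
        label=f"{mode}({', '.join(t.label for t in tracks)})",
        color=tracks[0].color, library_size=lib, units=tracks[0].units,
    )


def compute_psi(junctions: dict[Junction, float], target_exon: ExonBlock) -> PsiValue:
    """Junction-read PSI of ``target_exon`` against a junction count map.

    Inclusion: junctions whose acceptor equals the exon start (upstream
    flank) plus junctions whose donor equals the exon end (downstream
    flank).  Exclusion: junctions spanning the whole exon
    (donor <= start and acceptor >= end).  Undefined (value None) when both
    sums are zero.
    """
    inclusion = 0.0
    exclusion = 0.0
    for j, count in junctions.items():
        if j.acceptor == target_exon.start or j.donor == target_exon.end:
            inclusion += count
        elif j.donor <= target_exon.start and j.acceptor >= target_exon.end:
            exclusion += count
    total = inclusion + exclusion
    value = inclusion / total if total > 0 else None
    return PsiValue(value, int(inclusion), int(exclusion))
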