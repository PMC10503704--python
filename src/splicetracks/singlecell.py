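"""Single-cell demultiplexing: split a pooled alignment file into per-group
coverage tracks with UMI deduplication and strand-aware partitioning.

Reads are routed to groups through a user-supplied barcode table; within a
group, reads sharing (barcode, UMI, leftmost aligned position) collapse to a
single molecule before depth/junction computation.  Position is part of the
default dedup key so that distinct fragments with recycled UMIs survive; a
(barcode, UMI)-only key is available via ``dedup_on_position=False``.

Deduplication happens before strand splitting — strand never enters the
dedup key.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np

from .coverage import (
    CoverageTrack,
    MalformedCigarError,
    ReadFilters,
    _open_bam,
    mapped_read_count,
    rasterize,
    read_strand,
    segment_blocks,
)
from .regions import GenomicRegion, Junction

log = logging.getLogger(__name__)

__all__ = [
    "BarcodeTable",
    "DemuxStats",
    "read_barcode_table",
    "demultiplex",
    "strand_split",
    "transcribed_strand",
]


@dataclass
class BarcodeTable:
    """Mapping cell barcode -> group label; each barcode belongs to one group."""

    groups: dict[str, str]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("barcode table is empty")

    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups.values():
            seen.setdefault(g, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.groups)


def read_barcode_table(path) -> BarcodeTable:
    """Read a two-column (barcode, group) delimited file, TSV or CSV.

    An optional header row is detected by the literal words "barcode" /
    "cell" in the first column.  A barcode listed twice with the same group
    is accepted once; with conflicting groups it is an error naming the
    barcode.
    """
    groups: dict[str, str] = {}
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        try:
            dialect = csv.Sniffer().sniff(sample, delimiters="\t,; ")
        except csv.Error:
            dialect = csv.excel_tab
        for i, row in enumerate(csv.reader(fh, dialect)):
            if not row or not row[0].strip():
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: row {i + 1} has fewer than 2 columns")
            bc, grp = row[0].strip(), row[1].strip()
            if i == 0 and bc.lower() in ("barcode", "cell", "cell_barcode", "cb"):
                continue
            if bc in groups and groups[bc] != grp:
                raise ValueError(
                    f"{path}: barcode {bc!r} assigned to both "
                    f"{groups[bc]!r} and {grp!r}"
                )
            groups[bc] = grp
    return BarcodeTable(groups)


@dataclass
class DemuxStats:
    """Read accounting for one demultiplexing pass.

    Conservation invariant: used + dropped_barcode + duplicate_collapsed
    equals the total number of filter-passing reads in the window.
    """

    used: int = 0
    dropped_barcode: int = 0
    duplicate_collapsed: int = 0
    missing_umi: int = 0
    per_group_used: dict[str, int] = field(default_factory=dict)

    @property
    def total_passing(self) -> int:
        return self.used + self.dropped_barcode + self.duplicate_collapsed


def transcribed_strand(is_reverse: bool, strandness: str) -> str:
    """Infer the transcribed strand from the alignment flag and the library
    protocol: ``forward`` keeps the flag strand, ``reverse`` inverts it."""
    strand = "-" if is_reverse else "+"
    if strandness == "reverse":
        strand = "-" if strand == "+" else "+"
    elif strandness not in ("forward", "unstranded"):
        raise ValueError(f"unknown strandness {strandness!r}")
    return strand


def demultiplex(
    bam_path,
    region: GenomicRegion,
    table: BarcodeTable,
    filters: ReadFilters | None = None,
    barcode_tag: str = "CB",
    umi_tag: str = "UB",
    dedup_on_position: bool = True,
    strandness: str = "unstranded",
) -> tuple[dict[str, CoverageTrack], DemuxStats]:
    """Split the window's reads into one deduplicated CoverageTrack per group.

    Reads with an absent or unlisted barcode are dropped and counted.
    Reads with a barcode but no UMI are kept without deduplication and
    counted in a warning (fail-soft on mixed inputs).  Every group in the
    table gets a track, possibly all-zero.

    When ``strandness`` is forward/reverse, only reads whose transcribed
    strand matches ``region.strand`` are used (``region.strand == "."``
    keeps everything); use :func:`strand_split` for a sense/antisense pair.
    """
    filters = filters or ReadFilters(drop_duplicates=True)
    stats = DemuxStats(per_group_used={g: 0 for g in table.group_labels()})
    depth = {g: np.zeros(region.length(), dtype=float) for g in table.group_labels()}
    junctions: dict[str, dict[Junction, float]] = {g: {} for g in table.group_labels()}
    seen: set[tuple] = set()
    any_barcode = False

    bam, chrom = _open_bam(bam_path, region)
    with bam:
        library_size = mapped_read_count(bam)
        for seg in bam.fetch(chrom, region.start, region.end):
            if not filters.passes(seg):
                continue
            if not seg.has_tag(barcode_tag):
                stats.dropped_barcode += 1
                continue
            any_barcode = True
            bc = seg.get_tag(barcode_tag)
            group = table.groups.get(bc)
            if group is None:
                stats.dropped_barcode += 1
                continue
            if seg.has_tag(umi_tag):
                key = (bc, seg.get_tag(umi_tag))
                if dedup_on_position:
                    key = key + (seg.reference_start,)
                if key in seen:
                    stats.duplicate_collapsed += 1
                    continue
                seen.add(key)
            else:
                stats.missing_umi += 1
            if strandness != "unstranded" and region.strand != ".":
                if transcribed_strand(seg.is_reverse, strandness) != region.strand:
                    stats.dropped_barcode += 1
                    continue
            try:
                blocks, juncs = segment_blocks(seg)
            except MalformedCigarError:
                stats.dropped_barcode += 1
                continue
            stats.used += 1
            stats.per_group_used[group] += 1
            rasterize(blocks, region, depth[group])
            for j in juncs:
                if region.overlaps(j.donor, j.acceptor):
                    junctions[group][j] = junctions[group].get(j, 0) + 1

    if not any_barcode:
        log.warning("%s: no read in window carries tag %s", bam_path, barcode_tag)
    if stats.missing_umi:
        log.warning(
            "%s: %d reads had a barcode but no %s tag; kept without dedup",
            bam_path, stats.missing_umi, umi_tag,
        )
    tracks = {
        g: CoverageTrack(region, depth[g], junctions[g], label=g,
                         library_size=library_size)
        for g in table.group_labels()
    }
    return tracks, stats


def strand_split(
    bam_path,
    region: GenomicRegion,
    strandness: str,
    filters: ReadFilters | None = None,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Partition the window's reads into (sense, antisense) coverage tracks.

    The transcribed strand of each read is the alignment-flag strand,
    inverted for reverse-stranded libraries.  Sense means "+" here (tracks
    are relabeled by callers when the region is on the minus strand).  For
    unstranded libraries everything lands in sense and antisense is empty.
    """
    filters = filters or ReadFilters()
    sense_depth = np.zeros(region.length(), dtype=float)
    anti_depth = np.zeros(region.length(), dtype=float)
    sense_j: dict[Junction, float] = {}
    anti_j: dict[Junction, float] = {}
    bam, chrom = _open_bam(bam_path, region)
    with bam:
        library_size = mapped_read_count(bam)
        for seg in bam.fetch(chrom, region.start, region.end):
            if not filters.passes(seg):
                continue
            try:
                blocks, juncs = segment_blocks(seg)
            except MalformedCigarError:
                continue
            if strandness == "unstranded":
                to_sense = True
            else:
                to_sense = transcribed_strand(seg.is_reverse, strandness) == "+"
            depth, jmap = (sense_depth, sense_j) if to_sense else (anti_depth, anti_j)
            rasterize(blocks, region, depth)
            for j in juncs:
                if region.overlaps(j.donor, j.acceptor):
                    jmap[j] = jmap.get(j, 0) + 1
    sense = CoverageTrack(region, sense_depth, sense_j, label="sense",
                          library_size=library_size)
    anti = CoverageTrack(region, anti_depth, anti_j, label="antisense",
                         library_size=library_size, color="#e41a1c")
    return sense, anti
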