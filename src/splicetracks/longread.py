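"""Read-by-read extraction for long-read visualization.

Each passing read becomes a :class:`ReadRow`: its aligned exon blocks and
junction chain, plus optional decorations — poly(A)-tail length from a
numeric tag (with a soft-clip fallback) and base modifications from the
standard MM/ML tag pair.

"Exon sort" orders rows by their junction-chain signature so reads sharing
an exon-intron structure sit adjacent, making isoform structure visually
obvious; junction-free reads come last, by start position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam

from .coverage import MalformedCigarError, ReadFilters, _open_bam, segment_blocks
from .regions import ExonBlock, GenomicRegion, Junction

log = logging.getLogger(__name__)

__all__ = [
    "ReadRow",
    "collect_read_rows",
    "exon_sort",
    "extract_polya",
    "extract_mods",
]

DEFAULT_POLYA_TAG = "pa"
POLYA_CLIP_A_FRACTION = 0.8
DEFAULT_MOD_MIN_PROB = 0.5


@dataclass
class ReadRow:
    """One long read's displayable structure.

    ``blocks`` are clipped to the viewing window; ``junctions`` are not, so
    the full junction chain stays available for sorting/identity.  ``mods``
    holds (genomic position, modification code, probability) triples.
    """

    read_id: str
    blocks: list[ExonBlock]
    junctions: list[Junction]
    strand: str
    polya_len: int = 0
    mods: list[tuple[int, str, float]] = field(default_factory=list)


def extract_polya(
    seg: pysam.AlignedSegment,
    tag_name: str = DEFAULT_POLYA_TAG,
    clip_fallback: bool = False,
) -> int:
    """Poly(A)-tail length of one read in nt (0 = absent).

    The numeric tag ``tag_name`` wins when present; a negative value is
    treated as absent with a warning.  With ``clip_fallback``, a missing tag
    falls back to the terminal soft-clip at the read's 3' end when its
    A fraction (T for reverse-strand reads, whose stored sequence is
    reference-oriented) is at least 0.8.
    """
    if seg.has_tag(tag_name):
        value = seg.get_tag(tag_name)
        if value < 0:
            log.warning("%s: negative %s tag, treated as absent", seg.query_name, tag_name)
            return 0
        return int(value)
    if not clip_fallback:
        return 0
    cig = seg.cigartuples
    seq = seg.query_sequence
    if not cig or not seq:
        return 0
    # 3' end of the molecule: right end of SEQ for forward reads, left end
    # (as poly(T)) for reverse reads.
    if seg.is_reverse:
        if cig[0][0] != 4:
            return 0
        clip, base = seq[: cig[0][1]], "T"
    else:
        if cig[-1][0] != 4:
            return 0
        clip, base = seq[-cig[-1][1]:], "A"
    if clip and clip.upper().count(base) / len(clip) >= POLYA_CLIP_A_FRACTION:
        return len(clip)
    return 0


def extract_mods(
    seg: pysam.AlignedSegment, min_prob: float = DEFAULT_MOD_MIN_PROB
) -> list[tuple[int, str, float]]:
    """Decode MM/ML base-modification tags into genomic positions.

    ML byte b maps to probability (b + 0.5) / 256 (midpoint of the encoded
    bin); MM without ML yields probability 1.0 with a warning.  Read bases
    without a genomic image (insertions, soft clips) are dropped.  Only
    entries with probability >= ``min_prob`` are returned, sorted by
    position.
    """
    if not 0.0 <= min_prob <= 1.0:
        raise ValueError(f"min_prob must be in [0, 1], got {min_prob}")
    try:
        parsed = seg.modified_bases
    except Exception:  # malformed MM: skip this read's mods
        log.warning("%s: malformed MM tag, modifications skipped", seg.query_name)
        return []
    if not parsed:
        return []
    qpos_to_ref = {
        q: r for q, r in seg.get_aligned_pairs(matches_only=True) if q is not None
    }
    warned_no_ml = False
    out: list[tuple[int, str, float]] = []
    for (_canonical, _strand, code), entries in parsed.items():
        for qpos, qual in entries:
            if qual is None or qual < 0:
                prob = 1.0
                if not warned_no_ml:
                    log.warning("%s: MM without ML, probabilities set to 1.0",
                                seg.query_name)
                    warned_no_ml = True
            else:
                prob = (qual + 0.5) / 256.0
            if prob < min_prob:
                continue
            ref = qpos_to_ref.get(qpos)
            if ref is None:
                continue  # no genomic image (soft clip / insertion)
            out.append((ref, str(code), prob))
    out.sort()
    return out


def collect_read_rows(
    bam_path,
    region: GenomicRegion,
    filters: ReadFilters | None = None,
    polya_tag: str = DEFAULT_POLYA_TAG,
    polya_clip_fallback: bool = False,
    mod_min_prob: float = DEFAULT_MOD_MIN_PROB,
) -> list[ReadRow]:
    """One ReadRow per passing read overlapping the window.

    Blocks are clipped to the window for display; the junction list is left
    unclipped.  Secondary/supplementary alignments are excluded by the
    default filters.
    """
    filters = filters or ReadFilters()
    rows: list[ReadRow] = []
    bam, chrom = _open_bam(bam_path, region)
    with bam:
        for seg in bam.fetch(chrom, region.start, region.end):
            if not filters.passes(seg):
                continue
            try:
                blocks, junctions = segment_blocks(seg)
            except MalformedCigarError:
                continue
            clipped = []
            for b in blocks:
                lo, hi = max(b.start, region.start), min(b.end, region.end)
                if lo < hi:
                    clipped.append(ExonBlock(lo, hi))
            if not clipped:
                continue
            rows.append(
                ReadRow(
                    read_id=seg.query_name,
                    blocks=clipped,
                    junctions=junctions,
                    strand="-" if seg.is_reverse else "+",
                    polya_len=extract_polya(seg, polya_tag, polya_clip_fallback),
                    mods=extract_mods(seg, mod_min_prob),
                )
            )
    return rows


def _sort_key(row: ReadRow):
    # Spliced reads first, grouped by junction chain; junction-free reads
    # after them, by start.  Tertiary read_id makes the order total.
    chain = tuple((j.donor, j.acceptor) for j in row.junctions)
    start = row.blocks[0].start if row.blocks else 0
    return (0 if chain else 1, chain, start, row.read_id)


def exon_sort(rows: list[ReadRow]) -> list[ReadRow]:
    """Order rows by junction-chain signature (lexicographic on junction
    coordinates), then leftmost block start, then read_id.  Reads with
    identical exon-intron structure end up adjacent; the sort is a pure
    permutation and idempotent."""
    return sorted(rows, key=_sort_key)
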