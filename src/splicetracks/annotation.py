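"""Readers for transcript annotation: GTF and BED12.

Both readers return :class:`~splicetracks.regions.TranscriptModel` lists for
transcripts whose genomic span (first exon start to last exon end) overlaps
the query window — exon-level overlap is deliberately not required, so a
purely intronic window still shows the gene model, as a genome browser would.

GTF coordinates (1-based inclusive) and BED coordinates (0-based half-open)
are both converted to the package-internal 0-based half-open convention.
Gzipped files are accepted transparently (magic-byte sniff).
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from pathlib import Path

from .regions import ExonBlock, GenomicRegion, TranscriptModel

log = logging.getLogger(__name__)

__all__ = ["read_gtf", "read_bed12", "AnnotationError"]


class AnnotationError(ValueError):
    """Malformed annotation record that cannot be skipped safely."""


def _open_text(path) -> io.TextIOBase:
    """Open plain or gzipped text, sniffing the gzip magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _gtf_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path, region: GenomicRegion) -> list[TranscriptModel]:
    """Read every transcript overlapping ``region`` from a GTF file.

    Only ``exon`` and ``CDS`` feature lines are used; they are grouped by
    their ``transcript_id`` attribute.  The file need not be sorted or
    indexed — a full scan is performed.  Exon lines missing a
    transcript_id are skipped and counted in a log message.

    Returns transcripts sorted by (start, transcript_id).
    """
    exons: dict[str, list[ExonBlock]] = {}
    cds: dict[str, list[ExonBlock]] = {}
    meta: dict[str, tuple[str, str]] = {}  # tid -> (gene_id, strand)
    chrom_of: dict[str, str] = {}
    skipped = 0
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                skipped += 1
                continue
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts[:9]
            if feature not in ("exon", "CDS"):
                continue
            if _chrom_mismatch(chrom, region.chrom):
                continue
            attr = _gtf_attributes(attrs)
            tid = attr.get("transcript_id")
            if not tid:
                skipped += 1
                continue
            block = ExonBlock(int(start) - 1, int(end))  # GTF is 1-based inclusive
            chrom_of[tid] = chrom
            meta.setdefault(tid, (attr.get("gene_id", ""), strand))
            (exons if feature == "exon" else cds).setdefault(tid, []).append(block)
    if skipped:
        log.warning("read_gtf(%s): skipped %d malformed/ID-less lines", path, skipped)

    out = []
    for tid, ex in exons.items():
        gene_id, strand = meta[tid]
        tm = TranscriptModel(tid, gene_id, strand, ex, cds.get(tid, []))
        if tm.span_overlaps(region):
            out.append(tm)
    out.sort(key=lambda t: (t.start, t.transcript_id))
    return out


def _chrom_mismatch(a: str, b: str) -> bool:
    """True if names differ even after the chr-prefix alias pass."""
    strip = lambda n: n[3:] if n.startswith("chr") else n
    return strip(a) != strip(b)


def read_bed12(path, region: GenomicRegion) -> list[TranscriptModel]:
    """Read transcripts overlapping ``region`` from a BED12 file.

    Exons are reconstructed from blockCount/blockSizes/blockStarts; CDS
    blocks are the exon intersections with [thickStart, thickEnd).  A line
    whose blockCount disagrees with its size/start lists is rejected with
    :class:`AnnotationError`.
    """
    out = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise AnnotationError(f"{path}:{ln}: expected 12 BED columns, got {len(parts)}")
            chrom, chrom_start, _chrom_end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5]
            thick_start, thick_end = int(parts[6]), int(parts[7])
            n_blocks = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",") if x]
            starts = [int(x) for x in parts[11].rstrip(",").split(",") if x]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise AnnotationError(
                    f"{path}:{ln}: blockCount={n_blocks} but "
                    f"{len(sizes)} sizes / {len(starts)} starts listed"
                )
            if _chrom_mismatch(chrom, region.chrom):
                continue
            exons = [
                ExonBlock(chrom_start + off, chrom_start + off + size)
                for off, size in zip(starts, sizes)
            ]
            cds = []
            if thick_end > thick_start:
                for e in exons:
                    lo, hi = max(e.start, thick_start), min(e.end, thick_end)
                    if lo < hi:
                        cds.append(ExonBlock(lo, hi))
            tm = TranscriptModel(name, name, strand, exons, cds)
            if tm.span_overlaps(region):
                out.append(tm)
    out.sort(key=lambda t: (t.start, t.transcript_id))
    return out
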