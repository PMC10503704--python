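"""Shared genomic data types and coordinate conventions.

All internal coordinates are 0-based half-open intervals (BAM/BED style).
User-facing region strings are 1-based inclusive, browser style
(``chr1:1,000-2,000`` or ``chr1:1,000-2,000:+``).  ``parse_region`` and
``GenomicRegion.__str__`` perform the conversion; nothing else in the
package ever adds or subtracts 1.

Strand ``"."`` means unstranded / both; every strand filter in the package
treats ``"."`` as pass-all.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "GenomicRegion",
    "ExonBlock",
    "TranscriptModel",
    "Junction",
    "RegionParseError",
    "parse_region",
    "resolve_chrom",
]


class RegionParseError(ValueError):
    """Raised when a region string cannot be interpreted."""


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A half-open genomic window ``[start, end)`` on ``chrom``.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name.  Dialect ("chr1" vs "1") is reconciled
        lazily by :func:`resolve_chrom` at file-access time.
    start, end : int
        0-based half-open coordinates in bp; ``0 <= start < end``.
    strand : str
        One of ``"+"``, ``"-"``, ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be +, - or ., got {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, start: int, end: int) -> bool:
        """Half-open interval overlap with ``[start, end)``."""
        return start < self.end and end > self.start

    def __str__(self) -> str:
        """Canonical 1-based inclusive form, round-trippable by parse_region."""
        base = f"{self.chrom}:{self.start + 1}-{self.end}"
        if self.strand != ".":
            base += f":{self.strand}"
        return base


@dataclass(frozen=True, order=True)
class ExonBlock:
    """A half-open genomic interval ``[start, end)``, start < end."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty or inverted block [{self.start}, {self.end})")

    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class Junction:
    """A splice junction, stored as the removed intron ``[donor, acceptor)``.

    ``donor`` is the first intronic base, ``acceptor`` one past the last —
    exactly the reference span of the N operation in a spliced alignment.
    Identifying junctions by the intron interval makes their identity
    independent of where the supporting reads start and end.
    """

    donor: int
    acceptor: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.donor < self.acceptor:
            raise ValueError(f"require donor < acceptor, got {self.donor}, {self.acceptor}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad junction strand {self.strand!r}")


@dataclass
class TranscriptModel:
    """Exon/CDS block structure of one annotated isoform.

    ``exons`` must be sorted by start and non-overlapping; every CDS block
    must lie inside the exon union.  Both are enforced at construction.
    """

    transcript_id: str
    gene_id: str
    strand: str
    exons: list[ExonBlock] = field(default_factory=list)
    cds: list[ExonBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons {a} and {b}"
                )
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise ValueError(
                    f"{self.transcript_id}: CDS block {c} not contained in any exon"
                )

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def cds_length(self) -> int:
        return sum(c.length() for c in self.cds)

    def span_overlaps(self, region: GenomicRegion) -> bool:
        """Overlap judged on the genomic span (first exon start to last exon
        end) so that intronic query windows still display the gene model."""
        return bool(self.exons) and region.overlaps(self.start, self.end)

    def introns(self) -> list[ExonBlock]:
        return [
            ExonBlock(a.end, b.start)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]


_REGION_RE = re.compile(
    r"^(?P<chrom>[^:\s]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)(?::(?P<strand>[+\-.]))?$"
)


def parse_region(text: str) -> GenomicRegion:
    """Parse a browser-style region string into a :class:`GenomicRegion`.

    The input is 1-based inclusive (``chr1:1,000-2,000`` spans 1001 bases);
    commas in numbers are permitted.  An optional trailing ``:+``/``:-``
    sets the strand, which defaults to ``"."``.

    Raises
    ------
    RegionParseError
        On malformed syntax, non-positive coordinates, or start > end; the
        message names the offending token.
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise RegionParseError(f"malformed region string: {text!r}")
    start = int(m["start"].replace(",", ""))
    end = int(m["end"].replace(",", ""))
    if start < 1:
        raise RegionParseError(f"coordinates are 1-based; got start={m['start']!r}")
    if start > end:
        raise RegionParseError(
            f"inverted interval in {text!r}: start {start} > end {end}"
        )
    return GenomicRegion(m["chrom"], start - 1, end, m["strand"] or ".")


def resolve_chrom(name: str, available) -> str | None:
    """Reconcile chromosome-name dialects against a container of names.

    Tries the literal name, then with a ``chr`` prefix added or stripped.
    Returns the matching name from ``available``, or ``None``.
    """
    names = set(available)
    if name in names:
        return name
    alt = name[3:] if name.startswith("chr") else "chr" + name
    if alt in names:
        return alt
    return None
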