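"""Synthetic-data generation for offline, fully specified test inputs.

Every generator here writes a toy-scale file in one of the formats the
readers consume — BAM (+index), GTF, BED12, bedGraph, bigWig, samtools-depth
TSV, HiCExplorer-style h5, barcode tables — together with a ground-truth
manifest computed *from the construction parameters*, never by re-parsing
the written file.  The manifest (depth array, junction counts, PSI, dedup
accounting) is the oracle the engine is tested against.

No error model is simulated: reads are exact, deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pysam

from .regions import ExonBlock, GenomicRegion, Junction, TranscriptModel

__all__ = [
    "GeneFixture",
    "ReadSpec",
    "ReadSetFixture",
    "make_gene",
    "make_reads",
    "make_random_reads",
    "write_bam",
    "make_signal",
    "make_contacts",
    "write_barcode_table",
]

DEFAULT_CHROM = "chr1"
DEFAULT_CHROM_LEN = 1_000_000


# --- annotation -------------------------------------------------------------


@dataclass
class GeneFixture:
    """One synthetic gene in three mutually consistent representations."""

    transcript: TranscriptModel
    chrom: str
    gtf_text: str
    bed12_text: str

    def write_gtf(self, path) -> Path:
        path = Path(path)
        path.write_text(self.gtf_text)
        return path

    def write_bed12(self, path) -> Path:
        path = Path(path)
        path.write_text(self.bed12_text)
        return path


def make_gene(
    exon_lengths: list[int],
    intron_lengths: list[int],
    strand: str = "+",
    cds_span: tuple[int, int] | None = None,
    offset: int = 10_000,
    chrom: str = DEFAULT_CHROM,
    transcript_id: str = "TX1",
    gene_id: str = "G1",
    stop_in_cds: bool = False,
) -> GeneFixture:
    """Build one synthetic transcript plus equivalent GTF and BED12 text.

    ``cds_span`` is a genomic (start, end) interval intersected with the
    exons to form CDS blocks; with ``stop_in_cds`` the GTF CDS lines cover
    the full span (stop codon included, as some annotation dialects do),
    otherwise the last 3 coding bases are excluded from the CDS lines while
    the BED thick interval always covers the full span.
    """
    if len(intron_lengths) != len(exon_lengths) - 1:
        raise ValueError("need exactly one intron length between consecutive exons")
    exons = []
    pos = offset
    for i, elen in enumerate(exon_lengths):
        exons.append(ExonBlock(pos, pos + elen))
        pos += elen
        if i < len(intron_lengths):
            pos += intron_lengths[i]
    cds_blocks: list[ExonBlock] = []
    if cds_span is not None:
        lo, hi = cds_span
        for e in exons:
            a, b = max(e.start, lo), min(e.end, hi)
            if a < b:
                cds_blocks.append(ExonBlock(a, b))
    tm = TranscriptModel(transcript_id, gene_id, strand, exons, cds_blocks)

    gtf_cds = list(cds_blocks)
    if gtf_cds and not stop_in_cds:
        gtf_cds = _trim_stop(gtf_cds, strand)
    lines = []
    for e in exons:
        lines.append(_gtf_line(chrom, "exon", e, strand, gene_id, transcript_id))
    for c in gtf_cds:
        lines.append(_gtf_line(chrom, "CDS", c, strand, gene_id, transcript_id))
    gtf_text = "\n".join(lines) + "\n"

    chrom_start = exons[0].start
    sizes = ",".join(str(e.length()) for e in exons)
    starts = ",".join(str(e.start - chrom_start) for e in exons)
    if cds_blocks:
        thick_start, thick_end = cds_blocks[0].start, cds_blocks[-1].end
    else:
        thick_start = thick_end = chrom_start
    bed12_text = "\t".join(
        str(x)
        for x in (
            chrom, chrom_start, exons[-1].end, transcript_id, 0, strand,
            thick_start, thick_end, 0, len(exons), sizes, starts,
        )
    ) + "\n"
    return GeneFixture(tm, chrom, gtf_text, bed12_text)


def _trim_stop(cds: list[ExonBlock], strand: str) -> list[ExonBlock]:
    """Remove the last 3 coding bases (the stop codon) from sorted CDS blocks."""
    remaining = 3
    blocks = [[c.start, c.end] for c in cds]
    order = reversed(range(len(blocks))) if strand == "+" else range(len(blocks))
    out = {i: blocks[i] for i in range(len(blocks))}
    for i in order:
        s, e = out[i]
        take = min(remaining, e - s)
        if strand == "+":
            out[i] = [s, e - take]
        else:
            out[i] = [s + take, e]
        remaining -= take
        if remaining == 0:
            break
    return [ExonBlock(s, e) for s, e in (out[i] for i in sorted(out)) if e > s]


def _gtf_line(chrom, feature, block: ExonBlock, strand, gene_id, transcript_id) -> str:
    attrs = f'gene_id "{gene_id}"; transcript_id "{transcript_id}";'
    return "\t".join(
        str(x)
        for x in (chrom, "synthetic", feature, block.start + 1, block.end,
                  ".", strand, ".", attrs)
    )


# --- reads ------------------------------------------------------------------


@dataclass
class ReadSpec:
    """Construction plan for one read; blocks are the ground truth from
    which both the CIGAR and the oracle manifest are derived."""

    name: str
    blocks: list[ExonBlock]
    is_reverse: bool = False
    mapq: int = 60
    tags: dict = field(default_factory=dict)
    soft_clip_3p: str = ""  # appended at the molecule's 3' end

    @property
    def start(self) -> int:
        return self.blocks[0].start

    def cigar(self) -> str:
        parts = []
        clip5 = clip3 = ""
        if self.soft_clip_3p:
            s = f"{len(self.soft_clip_3p)}S"
            clip5, clip3 = (s, "") if self.is_reverse else ("", s)
        parts.append(clip5)
        for i, b in enumerate(self.blocks):
            if i:
                parts.append(f"{b.start - self.blocks[i - 1].end}N")
            parts.append(f"{b.length()}M")
        parts.append(clip3)
        return "".join(parts)

    def junctions(self) -> list[Junction]:
        return [
            Junction(a.end, b.start)
            for a, b in zip(self.blocks, self.blocks[1:])
        ]

    def sequence(self) -> str:
        body = "C" * sum(b.length() for b in self.blocks)
        if not self.soft_clip_3p:
            return body
        return (self.soft_clip_3p + body) if self.is_reverse else (body + self.soft_clip_3p)


@dataclass
class ReadSetFixture:
    """A written BAM plus its construction-time ground truth."""

    bam_path: Path
    reads: list[ReadSpec]
    chrom: str
    manifest: dict

    def write_manifest(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.manifest, indent=1))
        return path


def oracle_depth(reads: list[ReadSpec], region: GenomicRegion) -> np.ndarray:
    """Brute-force per-read, per-base rasterizer over construction blocks."""
    depth = np.zeros(region.length(), dtype=float)
    for r in reads:
        covered = set()
        for b in r.blocks:
            for pos in range(b.start, b.end):
                if region.contains(pos):
                    covered.add(pos)
        for pos in covered:
            depth[pos - region.start] += 1
    return depth


def oracle_junctions(reads: list[ReadSpec], region: GenomicRegion) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in reads:
        for j in r.junctions():
            if region.overlaps(j.donor, j.acceptor):
                key = f"{j.donor}-{j.acceptor}"
                counts[key] = counts.get(key, 0) + 1
    return counts


def write_bam(
    reads: list[ReadSpec],
    out_path,
    chrom: str = DEFAULT_CHROM,
    chrom_length: int = DEFAULT_CHROM_LEN,
) -> Path:
    """Write coordinate-sorted, indexed BAM from read specs."""
    out_path = Path(out_path)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": chrom_length}],
    }
    with pysam.AlignmentFile(str(out_path), "wb", header=header) as bam:
        # stable sort by coordinate only: ties keep caller order, so a
        # shuffled read list genuinely changes the file's record order
        for spec in sorted(reads, key=lambda r: r.start):
            seg = pysam.AlignedSegment(bam.header)
            seg.query_name = spec.name
            seg.reference_id = 0
            seg.reference_start = spec.start
            seg.mapping_quality = spec.mapq
            seg.cigarstring = spec.cigar()
            seg.flag = 16 if spec.is_reverse else 0
            seq = spec.sequence()
            seg.query_sequence = seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            for tag, value in spec.tags.items():
                seg.set_tag(tag, value)
            bam.write(seg)
    pysam.index(str(out_path))
    return out_path


def make_reads(
    transcript: TranscriptModel,
    out_path,
    n_inclusion: int = 60,
    n_exclusion: int = 40,
    target_exon_index: int = 1,
    anchor: int = 50,
    barcodes: list[str] | None = None,
    umis: list[str] | None = None,
    tags: dict | None = None,
    chrom: str = DEFAULT_CHROM,
    chrom_length: int = DEFAULT_CHROM_LEN,
    seed: int = 0,
) -> ReadSetFixture:
    """Write a BAM exercising inclusion/exclusion of one cassette exon.

    Inclusion reads alternate between the upstream junction (flanking exon
    into the target) and the downstream junction (target into the next
    exon); exclusion reads splice straight over the target.  With barcode /
    UMI lists given, CB/UB tags are assigned round-robin.  The manifest
    records ground-truth depth, junction counts, and the junction-read PSI
    (inclusion / (inclusion + exclusion)) by construction.
    """
    rng = np.random.default_rng(seed)
    exons = transcript.exons
    if not 0 < target_exon_index < len(exons) - 1:
        raise ValueError("target exon must be internal")
    up, target, down = (
        exons[target_exon_index - 1],
        exons[target_exon_index],
        exons[target_exon_index + 1],
    )
    a = min(anchor, up.length(), target.length(), down.length())
    reads: list[ReadSpec] = []

    def decorate(i: int) -> dict:
        t = dict(tags or {})
        if barcodes:
            t["CB"] = barcodes[i % len(barcodes)]
        if umis:
            t["UB"] = umis[i % len(umis)]
        return t

    for i in range(n_inclusion):
        if i % 2 == 0:
            blocks = [ExonBlock(up.end - a, up.end), ExonBlock(target.start, target.start + a)]
        else:
            blocks = [ExonBlock(target.end - a, target.end), ExonBlock(down.start, down.start + a)]
        reads.append(ReadSpec(f"inc{i}", blocks, tags=decorate(i)))
    for i in range(n_exclusion):
        blocks = [ExonBlock(up.end - a, up.end), ExonBlock(down.start, down.start + a)]
        reads.append(ReadSpec(f"exc{i}", blocks, tags=decorate(n_inclusion + i)))
    rng.shuffle(reads)  # write order must not matter to the engine

    region = GenomicRegion(chrom, transcript.start, transcript.end)
    total = n_inclusion + n_exclusion
    manifest = {
        "region": str(region),
        "depth": oracle_depth(reads, region).tolist(),
        "junctions": oracle_junctions(reads, region),
        "psi": {
            "target_exon": [target.start, target.end],
            "inclusion": n_inclusion,
            "exclusion": n_exclusion,
            "value": (n_inclusion / total) if total else None,
        },
        "n_reads": total,
    }
    bam_path = write_bam(reads, out_path, chrom, chrom_length)
    return ReadSetFixture(bam_path, reads, chrom, manifest)


def make_random_reads(
    out_path,
    n_reads: int = 100,
    region_start: int = 10_000,
    region_end: int = 20_000,
    max_blocks: int = 4,
    chrom: str = DEFAULT_CHROM,
    chrom_length: int = DEFAULT_CHROM_LEN,
    seed: int = 0,
) -> ReadSetFixture:
    """Write a BAM of randomized (seeded) spliced reads with its oracle
    manifest over [region_start, region_end)."""
    rng = np.random.default_rng(seed)
    reads: list[ReadSpec] = []
    for i in range(n_reads):
        n_blocks = int(rng.integers(1, max_blocks + 1))
        pos = int(rng.integers(region_start, region_end - 600))
        blocks = []
        for _ in range(n_blocks):
            blen = int(rng.integers(20, 120))
            blocks.append(ExonBlock(pos, pos + blen))
            pos += blen + int(rng.integers(50, 400))
        reads.append(ReadSpec(f"r{i}", blocks, is_reverse=bool(rng.integers(2))))
    region = GenomicRegion(chrom, region_start, region_end)
    manifest = {
        "region": str(region),
        "depth": oracle_depth(reads, region).tolist(),
        "junctions": oracle_junctions(reads, region),
        "n_reads": n_reads,
    }
    bam_path = write_bam(reads, out_path, chrom, chrom_length)
    return ReadSetFixture(bam_path, reads, chrom, manifest)


# --- continuous signal ------------------------------------------------------


def make_signal(
    intervals: list[tuple[int, int, float]],
    out_dir,
    chrom: str = DEFAULT_CHROM,
    chrom_length: int = DEFAULT_CHROM_LEN,
    stem: str = "signal",
) -> dict[str, Path]:
    """Write the same step signal as bedGraph, bigWig, and samtools-depth TSV.

    ``intervals`` are non-overlapping, sorted (start, end, value) triples in
    0-based half-open coordinates; the three encodings agree by
    construction.
    """
    import pyBigWig

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    intervals = sorted(intervals)
    for (s1, e1, _), (s2, _, _) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError("intervals must be non-overlapping")

    bedgraph = out_dir / f"{stem}.bedgraph"
    bedgraph.write_text(
        "".join(f"{chrom}\t{s}\t{e}\t{v:g}\n" for s, e, v in intervals)
    )

    depth_tsv = out_dir / f"{stem}.depth.tsv"
    with open(depth_tsv, "w") as fh:
        for s, e, v in intervals:
            for pos in range(s, e):
                fh.write(f"{chrom}\t{pos + 1}\t{v:g}\n")

    bigwig = out_dir / f"{stem}.bw"
    bw = pyBigWig.open(str(bigwig), "w")
    bw.addHeader([(chrom, chrom_length)])
    if intervals:
        bw.addEntries(
            [chrom] * len(intervals),
            [s for s, _, _ in intervals],
            ends=[e for _, e, _ in intervals],
            values=[float(v) for _, _, v in intervals],
        )
    bw.close()
    return {"bedgraph": bedgraph, "bigwig": bigwig, "depth": depth_tsv}


# --- contact matrices -------------------------------------------------------


def make_contacts(
    out_path,
    n_bins: int = 10,
    bin_size: int = 10_000,
    start: int = 0,
    chrom: str = DEFAULT_CHROM,
    pattern: str = "decay",
    seed: int = 0,
) -> np.ndarray:
    """Write a HiCExplorer-layout h5 contact matrix and return the dense
    symmetric matrix that was stored.

    ``pattern`` "decay" gives distance-decaying counts plus seeded noise;
    "uniform" gives constant counts.
    """
    from scipy.sparse import csr_matrix

    rng = np.random.default_rng(seed)
    i, j = np.meshgrid(np.arange(n_bins), np.arange(n_bins), indexing="ij")
    if pattern == "decay":
        mat = 100.0 / (1.0 + np.abs(i - j)) + rng.integers(0, 5, (n_bins, n_bins))
        mat = np.triu(mat)
        mat = mat + np.triu(mat, 1).T  # symmetric by construction
    elif pattern == "uniform":
        mat = np.full((n_bins, n_bins), 10.0)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    sparse = csr_matrix(mat)
    with h5py.File(out_path, "w") as h5:
        iv = h5.create_group("intervals")
        iv.create_dataset(
            "chr_list", data=np.array([chrom.encode()] * n_bins)
        )
        iv.create_dataset(
            "start_list", data=start + np.arange(n_bins) * bin_size
        )
        iv.create_dataset(
            "end_list", data=start + (np.arange(n_bins) + 1) * bin_size
        )
        iv.create_dataset("extra_list", data=np.array([b"."] * n_bins))
        mg = h5.create_group("matrix")
        mg.create_dataset("data", data=sparse.data)
        mg.create_dataset("indices", data=sparse.indices)
        mg.create_dataset("indptr", data=sparse.indptr)
        mg.create_dataset("shape", data=np.array(sparse.shape))
    return mat


def write_barcode_table(
    groups: dict[str, str], path, delimiter: str = "\t", header: bool = False
) -> Path:
    path = Path(path)
    lines = []
    if header:
        lines.append(f"barcode{delimiter}group")
    lines.extend(f"{bc}{delimiter}{grp}" for bc, grp in groups.items())
    path.write_text("\n".join(lines) + "\n")
    return path
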