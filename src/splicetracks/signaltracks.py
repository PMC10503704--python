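"""Continuous-signal readers: bigWig, bedGraph, samtools-depth TSV, bigBed,
and HiCExplorer-style h5 contact matrices.

All per-base readers return a :class:`SignalTrack` whose array covers the
query window exactly; positions without data are 0, never NaN, so signal
panels render like coverage panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pyBigWig

from .annotation import _open_text
from .regions import GenomicRegion, resolve_chrom

log = logging.getLogger(__name__)

__all__ = [
    "SignalTrack",
    "ContactMatrix",
    "read_bigwig",
    "read_bigbed",
    "read_bedgraph",
    "read_depth_tsv",
    "read_contact_matrix",
]


@dataclass
class SignalTrack:
    """Per-base signal values over one region (missing data = 0)."""

    region: GenomicRegion
    values: np.ndarray
    label: str = ""
    color: str = "#4daf4a"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.region.length(),):
            raise ValueError(
                f"values length {self.values.shape} != region length "
                f"{self.region.length()}"
            )


@dataclass
class ContactMatrix:
    """Symmetric contact counts between genomic bins intersecting a region."""

    bin_size: int
    bins: list[GenomicRegion]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.bins)
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix shape {self.matrix.shape} != ({n}, {n})")
        if not np.allclose(self.matrix, self.matrix.T, rtol=1e-6, atol=1e-8):
            raise ValueError("contact matrix not symmetric")
        if (self.matrix < 0).any():
            raise ValueError("negative contact values")


def read_bigwig(path, region: GenomicRegion, label: str = "", color: str = "#4daf4a") -> SignalTrack:
    """Per-base values from a bigWig over the window; NaN and uncovered
    intervals become 0."""
    bw = pyBigWig.open(str(path))
    try:
        chrom = resolve_chrom(region.chrom, bw.chroms().keys())
        if chrom is None:
            raise ValueError(f"chromosome {region.chrom!r} absent from {path}")
        chrom_len = bw.chroms()[chrom]
        values = np.zeros(region.length(), dtype=float)
        hi = min(region.end, chrom_len)
        if region.start < hi:
            raw = np.asarray(bw.values(chrom, region.start, hi), dtype=float)
            raw[np.isnan(raw)] = 0.0
            values[: hi - region.start] = raw
    finally:
        bw.close()
    return SignalTrack(region, values, label=label or str(path), color=color)


def read_bigbed(path, region: GenomicRegion, label: str = "", color: str = "#4daf4a") -> SignalTrack:
    """Interval occupancy (score where present, else 1) from a bigBed."""
    bb = pyBigWig.open(str(path))
    try:
        if not bb.isBigBed():
            raise ValueError(f"{path} is not a bigBed file")
        chrom = resolve_chrom(region.chrom, bb.chroms().keys())
        if chrom is None:
            raise ValueError(f"chromosome {region.chrom!r} absent from {path}")
        values = np.zeros(region.length(), dtype=float)
        entries = bb.entries(chrom, region.start, region.end) or []
        for start, end, rest in entries:
            score = 1.0
            if rest:
                fields = rest.split("\t")
                if len(fields) >= 2:
                    try:
                        score = float(fields[1])
                    except ValueError:
                        score = 1.0
            lo = max(start, region.start) - region.start
            hi = min(end, region.end) - region.start
            if hi > lo:
                values[lo:hi] = score
    finally:
        bb.close()
    return SignalTrack(region, values, label=label or str(path), color=color)


def read_bedgraph(path, region: GenomicRegion, label: str = "", color: str = "#4daf4a") -> SignalTrack:
    """Per-base values from a (possibly gzipped, possibly unsorted) bedGraph.

    Later lines overwrite earlier ones where intervals overlap.  Lines with
    a non-numeric value column are skipped and counted.
    """
    values = np.zeros(region.length(), dtype=float)
    skipped = 0
    strip = lambda n: n[3:] if n.startswith("chr") else n
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                skipped += 1
                continue
            chrom, start_s, end_s, value_s = parts[:4]
            if strip(chrom) != strip(region.chrom):
                continue
            try:
                start, end, value = int(start_s), int(end_s), float(value_s)
            except ValueError:
                skipped += 1
                continue
            lo = max(start, region.start) - region.start
            hi = min(end, region.end) - region.start
            if hi > lo:
                values[lo:hi] = value
    if skipped:
        log.warning("read_bedgraph(%s): skipped %d malformed lines", path, skipped)
    return SignalTrack(region, values, label=label or str(path), color=color)


def read_depth_tsv(path, region: GenomicRegion, label: str = "", color: str = "#4daf4a") -> SignalTrack:
    """Per-base values from a samtools-depth TSV (chrom, 1-based pos, depth)."""
    values = np.zeros(region.length(), dtype=float)
    skipped = 0
    strip = lambda n: n[3:] if n.startswith("chr") else n
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                skipped += 1
                continue
            chrom, pos_s, depth_s = parts[:3]
            if strip(chrom) != strip(region.chrom):
                continue
            try:
                pos0 = int(pos_s) - 1
                depth = float(depth_s)
            except ValueError:
                skipped += 1
                continue
            if region.contains(pos0):
                values[pos0 - region.start] = depth
    if skipped:
        log.warning("read_depth_tsv(%s): skipped %d malformed lines", path, skipped)
    return SignalTrack(region, values, label=label or str(path), color=color)


def read_contact_matrix(path, region: GenomicRegion) -> ContactMatrix:
    """Sub-matrix of Hi-C contacts whose bins intersect the window.

    Expects the HiCExplorer native h5 layout: an ``intervals`` group with
    chr_list/start_list/end_list and a ``matrix`` group holding a CSR
    triplet (data, indices, indptr, shape).  A stored triangle is
    symmetrized by the element-wise maximum of the matrix and its
    transpose (an already-symmetric matrix passes through unchanged).
    """
    with h5py.File(path, "r") as h5:
        for group in ("intervals", "matrix"):
            if group not in h5:
                raise ValueError(f"{path}: missing h5 group {group!r}")
        iv = h5["intervals"]
        for ds in ("chr_list", "start_list", "end_list"):
            if ds not in iv:
                raise ValueError(f"{path}: missing h5 dataset intervals/{ds}")
        chroms = [c.decode() if isinstance(c, bytes) else str(c) for c in iv["chr_list"][:]]
        starts = np.asarray(iv["start_list"][:], dtype=int)
        ends = np.asarray(iv["end_list"][:], dtype=int)
        mg = h5["matrix"]
        for ds in ("data", "indices", "indptr", "shape"):
            if ds not in mg:
                raise ValueError(f"{path}: missing h5 dataset matrix/{ds}")
        from scipy.sparse import csr_matrix  # local import: only Hi-C needs it

        shape = tuple(int(x) for x in mg["shape"][:])
        full = csr_matrix(
            (mg["data"][:], mg["indices"][:], mg["indptr"][:]), shape=shape
        ).toarray()

    strip = lambda n: n[3:] if n.startswith("chr") else n
    idx = [
        i
        for i in range(len(chroms))
        if strip(chroms[i]) == strip(region.chrom)
        and region.overlaps(int(starts[i]), int(ends[i]))
    ]
    if not idx:
        raise ValueError(f"no bins overlap region {region}")
    sub = full[np.ix_(idx, idx)]
    sub = np.maximum(sub, sub.T)
    bins = [
        GenomicRegion(region.chrom, int(starts[i]), int(ends[i])) for i in idx
    ]
    bin_size = int(ends[idx[0]] - starts[idx[0]])
    return ContactMatrix(bin_size, bins, sub)
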