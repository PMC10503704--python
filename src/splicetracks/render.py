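"""Coordinate shrinkage and figure composition.

The x-axis of every panel runs through a shared :class:`ShrinkMap`, a
piecewise-linear, strictly increasing map from genomic position to plot
position.  Exonic stretches keep their length; each inter-exon gap g is
compressed to ``max(ceil(g * intron_scale), 1)`` plot units, so exonic
detail dominates the axis while gaps stay strictly monotone.

:func:`compose_figure` stacks the panels — coverage with junction arcs and
optional PSI labels, continuous signal, read-by-read long-read rows with
poly(A) bars and modification dots, a rotated triangular Hi-C heatmap, and
the gene model with projected protein-domain segments — over that shared
axis and writes png/pdf/tiff/svg.  Vector outputs are byte-reproducible:
embedded dates and creator metadata are pinned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import PathPatch, Rectangle
from matplotlib.path import Path as MplPath

from .coverage import CoverageTrack, PsiValue
from .domains import DomainTrack
from .longread import ReadRow
from .regions import ExonBlock, GenomicRegion, TranscriptModel
from .signaltracks import ContactMatrix, SignalTrack

log = logging.getLogger(__name__)

__all__ = [
    "ShrinkMap",
    "FigureSpec",
    "build_shrink_map",
    "compose_figure",
]

DEFAULT_INTRON_SCALE = 0.05

# Pin everything that can leak a timestamp or an environment-dependent id
# into vector output, so identical inputs give identical bytes.
matplotlib.rcParams["svg.hashsalt"] = "splicetracks"
matplotlib.rcParams["pdf.compression"] = 0
_FIXED_METADATA = {"Date": None, "Creator": "splicetracks", "CreationDate": None}


@dataclass
class ShrinkMap:
    """Piecewise-linear genomic -> plot coordinate map over one region.

    ``anchors`` hold matched breakpoints (genomic, plot), both strictly
    increasing; positions between anchors interpolate linearly.  With
    ``intron_scale == 1`` the map is the identity.
    """

    region: GenomicRegion
    genomic: np.ndarray
    plot: np.ndarray
    intron_scale: float = DEFAULT_INTRON_SCALE

    def __post_init__(self) -> None:
        self.genomic = np.asarray(self.genomic, dtype=float)
        self.plot = np.asarray(self.plot, dtype=float)
        if self.genomic.shape != self.plot.shape or self.genomic.ndim != 1:
            raise ValueError("anchor arrays must be 1-D and matched")
        if (np.diff(self.genomic) <= 0).any() or (np.diff(self.plot) <= 0).any():
            raise ValueError("anchors must be strictly increasing in both axes")

    def transform(self, position) -> np.ndarray | float:
        """Map genomic position(s) to plot coordinates (monotone).

        Out-of-region positions are clamped to the region edge with a
        warning.
        """
        pos = np.asarray(position, dtype=float)
        lo, hi = self.genomic[0], self.genomic[-1]
        if (pos < lo).any() or (pos > hi).any():
            log.warning("transform: position outside region, clamping")
            pos = np.clip(pos, lo, hi)
        out = np.interp(pos, self.genomic, self.plot)
        return float(out) if np.isscalar(position) or out.ndim == 0 else out

    @property
    def plot_span(self) -> tuple[float, float]:
        return float(self.plot[0]), float(self.plot[-1])


def merge_blocks(blocks: list[ExonBlock]) -> list[ExonBlock]:
    """Union of possibly-overlapping intervals, sorted."""
    merged: list[list[int]] = []
    for b in sorted(blocks):
        if merged and b.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b.end)
        else:
            merged.append([b.start, b.end])
    return [ExonBlock(s, e) for s, e in merged]


def build_shrink_map(
    region: GenomicRegion,
    exon_union: list[ExonBlock],
    intron_scale: float = DEFAULT_INTRON_SCALE,
) -> ShrinkMap:
    """Build the intron-shrinkage map for a window.

    ``exon_union`` is the merged exon set of all displayed transcripts
    (blocks outside the window are clipped to it).  Exonic stretches map at
    unit scale; each gap between consecutive exons maps to
    ``max(ceil(gap * intron_scale), 1)`` units.  Flanks outside the
    outermost exons, and a window with no exons at all, stay at unit scale
    (identity).
    """
    if not 0 < intron_scale <= 1:
        raise ValueError(f"intron_scale must be in (0, 1], got {intron_scale}")
    clipped = []
    for b in merge_blocks(exon_union):
        lo, hi = max(b.start, region.start), min(b.end, region.end)
        if lo < hi:
            clipped.append(ExonBlock(lo, hi))
    genomic = [float(region.start)]
    plot = [float(region.start)]

    def advance(to_gpos: int, scale: float) -> None:
        gap = to_gpos - genomic[-1]
        if gap <= 0:
            return
        step = gap if scale == 1.0 else max(math.ceil(gap * scale), 1)
        genomic.append(float(to_gpos))
        plot.append(plot[-1] + step)

    for i, b in enumerate(clipped):
        # flank before the first exon stays unscaled; inter-exon gaps shrink
        advance(b.start, 1.0 if i == 0 else intron_scale)
        advance(b.end, 1.0)
    advance(region.end, 1.0)
    return ShrinkMap(region, np.array(genomic), np.array(plot), intron_scale)


@dataclass
class FigureSpec:
    """Figure-level output options."""

    width: float = 10.0
    height: float = 8.0
    dpi: int = 100
    output_format: str = "png"
    track_heights: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.dpi <= 0:
            raise ValueError("width, height and dpi must be positive")
        if self.output_format not in ("png", "pdf", "tiff", "svg"):
            raise ValueError(f"unsupported output format {self.output_format!r}")


# --- panel painters ---------------------------------------------------------


def _arc(ax, x0: float, x1: float, height: float, label: str, color: str) -> None:
    xm = (x0 + x1) / 2
    path = MplPath(
        [(x0, 0), (xm, 2 * height), (x1, 0)],
        [MplPath.MOVETO, MplPath.CURVE3, MplPath.CURVE3],
    )
    ax.add_patch(PathPatch(path, fill=False, lw=0.9, edgecolor=color))
    ax.annotate(label, (xm, height), ha="center", va="bottom", fontsize=6)


def _paint_coverage(
    ax, track: CoverageTrack, smap: ShrinkMap,
    psi: PsiValue | None, junction_threshold: int,
) -> None:
    x = smap.transform(np.arange(track.region.start, track.region.end))
    ax.fill_between(x, 0.0, track.depth, step="mid",
                    color=track.color, lw=0, alpha=0.9)
    ymax = float(track.depth.max()) if track.depth.size else 1.0
    ymax = ymax if ymax > 0 else 1.0
    arcs = sorted(
        (j, c) for j, c in track.junctions.items() if c >= junction_threshold
    )
    for j, count in arcs:
        x0 = smap.transform(max(j.donor, track.region.start))
        x1 = smap.transform(min(j.acceptor, track.region.end))
        h = 0.25 * ymax * math.log1p(count) / max(
            math.log1p(max(c for _, c in arcs)), 1e-9
        )
        _arc(ax, x0, x1, ymax * 0.55 + h, f"{int(count)}", track.color)
    label = track.label
    if psi is not None:
        label += f"\npsi = {psi:.3f}"
    ax.set_ylabel(label, rotation=0, ha="right", va="center", fontsize=7)
    ax.set_ylim(0, ymax * 1.6)


def _paint_signal(ax, track: SignalTrack, smap: ShrinkMap) -> None:
    x = smap.transform(np.arange(track.region.start, track.region.end))
    ax.fill_between(x, 0.0, track.values, step="mid", color=track.color, lw=0)
    ax.set_ylabel(track.label, rotation=0, ha="right", va="center", fontsize=7)
    top = float(np.max(track.values)) if track.values.size else 1.0
    ax.set_ylim(0, (top if top > 0 else 1.0) * 1.1)


def _paint_reads(ax, rows: list[ReadRow], smap: ShrinkMap, label: str) -> None:
    for y, row in enumerate(rows):
        x0 = smap.transform(row.blocks[0].start)
        x1 = smap.transform(row.blocks[-1].end)
        ax.plot([x0, x1], [y, y], color="#999999", lw=0.5, zorder=1)
        for b in row.blocks:
            bx0, bx1 = smap.transform(b.start), smap.transform(b.end)
            ax.add_patch(Rectangle((bx0, y - 0.35), bx1 - bx0, 0.7,
                                   facecolor="#555555", lw=0, zorder=2))
        if row.polya_len > 0:
            # red bar at the 3' end, width proportional to tail length
            anchor = row.blocks[-1].end if row.strand == "+" else row.blocks[0].start
            ax_x = smap.transform(anchor)
            w = (1 if row.strand == "+" else -1) * row.polya_len * 0.2
            ax.add_patch(Rectangle((ax_x, y - 0.25), w, 0.5,
                                   facecolor="#d62728", lw=0, zorder=3))
        for pos, _code, _prob in row.mods:
            ax.plot([smap.transform(pos)], [y], ".", color="#1f77b4",
                    ms=3, zorder=4)
    ax.set_ylim(-1, max(len(rows), 1))
    ax.set_yticks([])
    ax.set_ylabel(label, rotation=0, ha="right", va="center", fontsize=7)


def _paint_contacts(ax, cm: ContactMatrix, smap: ShrinkMap, log_scale: bool) -> None:
    # 45-degree rotated triangular heatmap: bin pair (i, j) becomes a
    # diamond centered at (mid(i,j), |i-j|/2) in transformed coordinates.
    n = len(cm.bins)
    values = np.log1p(cm.matrix) if log_scale else cm.matrix
    vmax = values.max() if values.size and values.max() > 0 else 1.0
    cmap = plt.get_cmap("Reds")
    centers = [smap.transform((b.start + b.end) / 2) for b in cm.bins]
    width = np.median(np.diff(centers)) if n > 1 else 1.0
    for i in range(n):
        for j in range(i, n):
            cx = (centers[i] + centers[j]) / 2
            cy = (j - i) / 2
            color = cmap(values[i, j] / vmax)
            diamond = MplPath(
                [(cx - width / 2, cy), (cx, cy + 0.5), (cx + width / 2, cy),
                 (cx, cy - 0.5), (cx - width / 2, cy)],
                closed=True,
            )
            ax.add_patch(PathPatch(diamond, facecolor=color, lw=0))
    ax.set_ylim(-0.5, n / 2 + 0.5)
    ax.set_yticks([])
    ax.set_ylabel("contacts", rotation=0, ha="right", va="center", fontsize=7)


def _paint_annotation(
    ax, transcripts: list[TranscriptModel],
    domains: dict[str, DomainTrack], smap: ShrinkMap,
) -> None:
    for y, tm in enumerate(transcripts):
        x0 = smap.transform(max(tm.start, smap.region.start))
        x1 = smap.transform(min(tm.end, smap.region.end))
        ax.plot([x0, x1], [y, y], color="black", lw=0.8, zorder=1)
        for e in tm.exons:
            lo, hi = max(e.start, smap.region.start), min(e.end, smap.region.end)
            if lo >= hi:
                continue
            ex0, ex1 = smap.transform(lo), smap.transform(hi)
            ax.add_patch(Rectangle((ex0, y - 0.2), ex1 - ex0, 0.4,
                                   facecolor="black", lw=0, zorder=2))
        for c in tm.cds:
            lo, hi = max(c.start, smap.region.start), min(c.end, smap.region.end)
            if lo >= hi:
                continue
            cx0, cx1 = smap.transform(lo), smap.transform(hi)
            ax.add_patch(Rectangle((cx0, y - 0.3), cx1 - cx0, 0.6,
                                   facecolor="black", lw=0, zorder=3))
        dom = domains.get(tm.transcript_id)
        if dom is not None:
            for seg, _desc in dom.segments:
                lo, hi = max(seg.start, smap.region.start), min(seg.end, smap.region.end)
                if lo >= hi:
                    continue
                dx0, dx1 = smap.transform(lo), smap.transform(hi)
                ax.add_patch(Rectangle((dx0, y - 0.45), dx1 - dx0, 0.9,
                                       facecolor="#f8c8dc", lw=0, zorder=0))
        ax.annotate(tm.transcript_id, (x0, y + 0.35), fontsize=6, va="bottom")
    ax.set_ylim(-1, max(len(transcripts), 1))
    ax.set_yticks([])
    ax.set_ylabel("annotation", rotation=0, ha="right", va="center", fontsize=7)


# --- figure composition -----------------------------------------------------


def compose_figure(
    tracks: list,
    out_path,
    spec: FigureSpec | None = None,
    annotation: list[TranscriptModel] | None = None,
    domains: dict[str, DomainTrack] | None = None,
    shrink: ShrinkMap | None = None,
    highlights: list[GenomicRegion] | None = None,
    psi: dict[int, PsiValue] | None = None,
    junction_threshold: int = 1,
    hic_log: bool = True,
) -> None:
    """Stack all panels over a shared (optionally shrunken) x-axis and write
    the image.

    ``tracks`` is an ordered list of CoverageTrack / SignalTrack /
    ContactMatrix / list-of-ReadRow panels; ``psi`` optionally maps a track
    index to the PSI annotation shown under its label.  The annotation
    panel, when given, is drawn last.  Input data is never mutated.
    """
    spec = spec or FigureSpec()
    if not tracks and not annotation:
        raise ValueError("nothing to draw: zero tracks and no annotation")
    region = _panel_region(tracks, annotation)
    if shrink is None:
        shrink = build_shrink_map(region, [], intron_scale=1.0)

    panels = list(tracks)
    n_panels = len(panels) + (1 if annotation is not None else 0)
    heights = spec.track_heights or _default_heights(panels, annotation)
    fig, axes = plt.subplots(
        n_panels, 1, sharex=True,
        figsize=(spec.width, spec.height),
        gridspec_kw={"height_ratios": heights},
        squeeze=False,
    )
    axes = axes.ravel()
    for i, panel in enumerate(panels):
        ax = axes[i]
        if isinstance(panel, CoverageTrack):
            _paint_coverage(ax, panel, shrink,
                            (psi or {}).get(i), junction_threshold)
        elif isinstance(panel, SignalTrack):
            _paint_signal(ax, panel, shrink)
        elif isinstance(panel, ContactMatrix):
            _paint_contacts(ax, panel, shrink, hic_log)
        elif isinstance(panel, list):  # read rows
            _paint_reads(ax, panel, shrink, "reads")
        else:
            raise TypeError(f"cannot draw panel of type {type(panel).__name__}")
    if annotation is not None:
        _paint_annotation(axes[-1], annotation, domains or {}, shrink)

    for ax in axes:
        for h in highlights or []:
            lo = max(h.start, region.start)
            hi = min(h.end, region.end)
            if lo < hi:
                ax.axvspan(shrink.transform(lo), shrink.transform(hi),
                           color="#fff3b0", alpha=0.5, zorder=-5)
        ax.spines[["top", "right"]].set_visible(False)
    axes[-1].set_xlim(*shrink.plot_span)
    axes[-1].set_xlabel(f"{region.chrom} ({region.start + 1:,}-{region.end:,})",
                        fontsize=8)
    fig.align_ylabels(axes)
    fig.subplots_adjust(left=0.22, right=0.97, hspace=0.35)
    _save(fig, out_path, spec)
    plt.close(fig)


def _panel_region(tracks, annotation) -> GenomicRegion:
    for t in tracks:
        if isinstance(t, (CoverageTrack, SignalTrack)):
            return t.region
        if isinstance(t, ContactMatrix) and t.bins:
            return GenomicRegion(t.bins[0].chrom, t.bins[0].start, t.bins[-1].end)
    if annotation:
        tm = annotation[0]
        return GenomicRegion("?", tm.start, tm.end)
    raise ValueError("no panel defines a region")


def _default_heights(panels, annotation) -> list[float]:
    heights = []
    for p in panels:
        if isinstance(p, list):
            heights.append(max(1.0, len(p) / 8))
        elif isinstance(p, ContactMatrix):
            heights.append(1.5)
        else:
            heights.append(1.0)
    if annotation is not None:
        heights.append(max(0.8, len(annotation) / 3))
    return heights


def _save(fig, out_path, spec: FigureSpec) -> None:
    fmt = spec.output_format
    kwargs: dict = {"dpi": spec.dpi, "format": fmt}
    if fmt in ("svg", "pdf"):
        kwargs["metadata"] = dict(_FIXED_METADATA)
        if fmt == "svg":
            kwargs["metadata"].pop("CreationDate")
    elif fmt == "tiff":
        kwargs["pil_kwargs"] = {"compression": None}
    try:
        fig.savefig(str(out_path), **kwargs)
    except OSError as exc:
        raise OSError(f"cannot write figure to {out_path}: {exc}") from exc
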