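"""Meta-file parsing: one row per data track.

The meta file is delimited text (TSV/CSV, sniffed) with a header naming at
least ``path`` and ``category``; ``label``, ``color``, ``strandness`` and
``group`` are optional, and unknown columns are ignored with a notice.
Validation problems across all rows are aggregated into a single error
report so a broken meta file is fixed in one pass.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

from matplotlib.colors import is_color_like

log = logging.getLogger(__name__)

__all__ = ["TrackEntry", "MetaError", "parse_meta", "CATEGORIES"]

CATEGORIES = (
    "bam", "bigwig", "bigbed", "bedgraph", "depth", "bed", "gtf", "hic",
    "sc-bam", "longread-bam",
)

# fixed palette cycle for rows without an explicit color
PALETTE = (
    "#377eb8", "#e41a1c", "#4daf4a", "#984ea3",
    "#ff7f00", "#a65628", "#f781bf", "#999999",
)


class MetaError(ValueError):
    """Aggregated meta-file validation failure; message lists every problem."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__(
            "invalid meta file:\n" + "\n".join(f"  - {p}" for p in problems)
        )


@dataclass
class TrackEntry:
    """One validated row of the meta file."""

    path: Path
    category: str
    label: str
    color: str
    strandness: str = "unstranded"
    group: str | None = None


def parse_meta(path) -> list[TrackEntry]:
    """Parse and validate the meta file into track entries.

    Defaults: label = file basename, color = palette cycle, strandness =
    unstranded.  All problems (missing track files, unknown categories,
    bad colors/strandness) are collected and raised together as
    :class:`MetaError`.
    """
    path = Path(path)
    if not path.exists():
        raise MetaError([f"meta file {path} does not exist"])
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        try:
            dialect = csv.Sniffer().sniff(sample, delimiters="\t,;")
        except csv.Error:
            dialect = csv.excel_tab
        reader = csv.DictReader(fh, dialect=dialect)
        if reader.fieldnames is None:
            raise MetaError([f"{path}: empty meta file"])
        fields = [f.strip().lower() for f in reader.fieldnames]
        reader.fieldnames = fields
        known = {"path", "category", "label", "color", "strandness", "group"}
        missing = {"path", "category"} - set(fields)
        if missing:
            raise MetaError(
                [f"{path}: header must name {sorted(missing)} column(s)"]
            )
        unknown = [f for f in fields if f not in known]
        if unknown:
            log.info("%s: ignoring unknown meta columns %s", path, unknown)

        entries: list[TrackEntry] = []
        problems: list[str] = []
        for i, row in enumerate(reader, 2):  # 2 = first data line
            track_path = Path((row.get("path") or "").strip())
            category = (row.get("category") or "").strip().lower()
            if not track_path.name:
                problems.append(f"row {i}: empty path")
                continue
            if category not in CATEGORIES:
                problems.append(
                    f"row {i}: unknown category {category!r} "
                    f"(expected one of {', '.join(CATEGORIES)})"
                )
            if not track_path.exists():
                problems.append(f"row {i}: track path {track_path} does not exist")
            color = (row.get("color") or "").strip() or PALETTE[len(entries) % len(PALETTE)]
            if not is_color_like(color):
                problems.append(f"row {i}: invalid color {color!r}")
            strandness = (row.get("strandness") or "").strip().lower() or "unstranded"
            if strandness not in ("forward", "reverse", "unstranded"):
                problems.append(f"row {i}: invalid strandness {strandness!r}")
            entries.append(
                TrackEntry(
                    path=track_path,
                    category=category,
                    label=(row.get("label") or "").strip() or track_path.name,
                    color=color,
                    strandness=strandness,
                    group=(row.get("group") or "").strip() or None,
                )
            )
    if problems:
        raise MetaError(problems)
    if not entries:
        raise MetaError([f"{path}: no track rows"])
    return entries
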