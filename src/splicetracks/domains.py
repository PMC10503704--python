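"""Protein-feature retrieval and genomic projection through the CDS.

A transcript's protein features (domains, regions, ...) live in amino-acid
coordinates.  To draw them under a gene model they are projected onto the
genome: amino acid k occupies CDS nucleotides [3(k-1), 3k) counted along the
mRNA in translation order (for minus-strand transcripts the walk runs from
the rightmost CDS base leftwards), and that nucleotide interval is mapped
through the ordered CDS blocks, splitting at introns.

Before projecting, the CDS length is validated against the protein length:
a coding sequence must be exactly three times the protein length (strict
mode), or 3*(length+1) for annotation dialects that include the stop codon
in their CDS lines.  Failing transcripts get no domain track.

Feature sources are offline-first: a pair of delimited files (transcript ->
protein mapping; per-protein features) is the primary path, with an optional
live REST layer (UniProt id-mapping + EBI protein features) behind the same
interface, cached on disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from .regions import ExonBlock, TranscriptModel

log = logging.getLogger(__name__)

__all__ = [
    "ProteinFeature",
    "DomainTrack",
    "OfflineDomainSource",
    "ApiDomainSource",
    "validate_cds",
    "project_feature",
    "build_domain_track",
]


@dataclass(frozen=True)
class ProteinFeature:
    """One protein feature in 1-based inclusive amino-acid coordinates."""

    protein_id: str
    feature_type: str
    description: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if not 1 <= self.aa_start <= self.aa_end:
            raise ValueError(
                f"bad feature bounds [{self.aa_start}, {self.aa_end}]"
            )

    def aa_span(self) -> int:
        return self.aa_end - self.aa_start + 1


@dataclass
class DomainTrack:
    """Protein features of one transcript projected to genomic segments."""

    transcript_id: str
    protein_id: str
    segments: list[tuple[ExonBlock, str]]


class OfflineDomainSource:
    """Feature source backed by two local delimited files.

    ``mapping_path``: lines ``transcript_id<TAB>protein_id`` (one per pair,
    order preserved, a transcript may map to several proteins).
    ``features_path``: lines
    ``protein_id<TAB>protein_length<TAB>type<TAB>description<TAB>aa_start<TAB>aa_end``.
    A line whose aa_end exceeds the protein length is dropped with a warning.
    """

    def __init__(self, mapping_path, features_path, cache_dir=None):
        self._mapping: dict[str, list[str]] = {}
        for line in Path(mapping_path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            tid, pid = line.split("\t")[:2]
            self._mapping.setdefault(tid, []).append(pid)
        self._length: dict[str, int] = {}
        self._features: dict[str, list[ProteinFeature]] = {}
        dropped = 0
        for line in Path(features_path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            pid, length_s, ftype, desc, a_s, a_e = line.split("\t")[:6]
            length = int(length_s)
            self._length[pid] = length
            self._features.setdefault(pid, [])
            feat = ProteinFeature(pid, ftype, desc, int(a_s), int(a_e))
            if feat.aa_end > length:
                dropped += 1
                continue
            self._features[pid].append(feat)
        if dropped:
            log.warning(
                "%s: dropped %d features exceeding their protein length",
                features_path, dropped,
            )
        self.cache_dir = Path(cache_dir) if cache_dir else None
        self.lookup_calls = 0  # exposed so the cache contract is testable

    def lookup_protein_ids(self, transcript_id: str) -> list[str]:
        """Protein IDs for a transcript, order preserved; [] when unknown.
        Results are cached on disk when a cache_dir is configured."""
        if self.cache_dir is not None:
            cache = self.cache_dir / f"map_{transcript_id}.json"
            if cache.exists():
                return json.loads(cache.read_text())
        self.lookup_calls += 1
        ids = list(self._mapping.get(transcript_id, []))
        if self.cache_dir is not None:
            self.cache_dir.mkdir(parents=True, exist_ok=True)
            (self.cache_dir / f"map_{transcript_id}.json").write_text(json.dumps(ids))
        return ids

    def fetch_features(
        self, protein_id: str, type_whitelist: set[str] | None = None
    ) -> tuple[int, list[ProteinFeature]]:
        """(protein_length, features), optionally filtered by feature type."""
        if protein_id not in self._length:
            raise KeyError(f"unknown protein id {protein_id!r}")
        feats = self._features.get(protein_id, [])
        if type_whitelist is not None:
            feats = [f for f in feats if f.feature_type in type_whitelist]
        return self._length[protein_id], list(feats)


class ApiDomainSource:
    """Live REST feature source (UniProt search + EBI protein features).

    Network access is entirely optional; responses are cached on disk so a
    region is fetched at most once.  Errors distinguish "cached copy
    available" from a genuinely unreachable source.
    """

    UNIPROT_URL = "https://rest.uniprot.org/uniprotkb/search?format=json&query={tid}"
    EBI_URL = "https://www.ebi.ac.uk/proteins/api/features/{pid}"

    def __init__(self, cache_dir, timeout: float = 10.0):
        self.cache_dir = Path(cache_dir)
        self.cache_dir.mkdir(parents=True, exist_ok=True)
        self.timeout = timeout

    def _get_json(self, url: str, cache_name: str):
        cache = self.cache_dir / cache_name
        if cache.exists():
            return json.loads(cache.read_text())
        import urllib.request

        try:
            with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                payload = json.loads(resp.read().decode())
        except Exception as exc:
            raise ConnectionError(
                f"could not reach {url} and no cached copy exists"
            ) from exc
        cache.write_text(json.dumps(payload))
        return payload

    def lookup_protein_ids(self, transcript_id: str) -> list[str]:
        payload = self._get_json(
            self.UNIPROT_URL.format(tid=transcript_id), f"map_{transcript_id}.json"
        )
        ids: list[str] = []
        for entry in payload.get("results", []):
            acc = entry.get("primaryAccession")
            if acc and acc not in ids:
                ids.append(acc)
        return ids

    def fetch_features(
        self, protein_id: str, type_whitelist: set[str] | None = None
    ) -> tuple[int, list[ProteinFeature]]:
        payload = self._get_json(
            self.EBI_URL.format(pid=protein_id), f"feat_{protein_id}.json"
        )
        length = int(payload.get("sequence") and len(payload["sequence"]) or 0)
        feats = []
        for f in payload.get("features", []):
            try:
                feat = ProteinFeature(
                    protein_id, f.get("type", ""), f.get("description", ""),
                    int(f["begin"]), int(f["end"]),
                )
            except (KeyError, ValueError):
                continue
            if type_whitelist is not None and feat.feature_type not in type_whitelist:
                continue
            if length and feat.aa_end > length:
                continue
            feats.append(feat)
        return length, feats


def validate_cds(
    transcript: TranscriptModel, protein_length: int, strict: bool = False
) -> bool:
    """True iff the transcript's CDS length matches the protein length.

    The rule is CDS length == 3 * protein_length.  Non-strict mode also
    accepts 3 * (protein_length + 1) to absorb annotation dialects that
    include the stop codon in their CDS lines.  A False result suppresses
    the domain track for this transcript.
    """
    cds_len = transcript.cds_length()
    if cds_len == 0:
        return False
    if cds_len == 3 * protein_length:
        return True
    return (not strict) and cds_len == 3 * (protein_length + 1)


def _cds_walk(transcript: TranscriptModel) -> list[ExonBlock]:
    """CDS blocks in translation order (5'->3' of the mRNA)."""
    blocks = sorted(transcript.cds)
    return blocks if transcript.strand == "+" else blocks[::-1]


def project_feature(
    transcript: TranscriptModel, feature: ProteinFeature
) -> list[ExonBlock]:
    """Project a protein feature onto genomic coordinates through the CDS.

    Amino acid k covers CDS-nucleotide interval [3(k-1), 3k) along the
    translation walk; the feature's nucleotide interval [3(aa_start-1),
    3*aa_end) is mapped block by block through the ordered CDS, splitting
    at intron boundaries.  Segments are returned in genomic order and are
    length-preserving: total bp == 3 * aa span.
    """
    nt_lo = 3 * (feature.aa_start - 1)
    nt_hi = 3 * feature.aa_end
    cds_len = transcript.cds_length()
    if nt_hi > cds_len:
        raise ValueError(
            f"feature [{feature.aa_start}, {feature.aa_end}] extends past "
            f"CDS of {cds_len // 3} codons"
        )
    segments: list[ExonBlock] = []
    offset = 0  # nt consumed along the translation walk
    for block in _cds_walk(transcript):
        blen = block.length()
        lo = max(nt_lo, offset)
        hi = min(nt_hi, offset + blen)
        if lo < hi:
            if transcript.strand == "+":
                segments.append(ExonBlock(block.start + (lo - offset),
                                          block.start + (hi - offset)))
            else:
                # walk enters this block at its right edge
                segments.append(ExonBlock(block.end - (hi - offset),
                                          block.end - (lo - offset)))
        offset += blen
    segments.sort()
    return segments


def genomic_to_aa(transcript: TranscriptModel, pos: int) -> int | None:
    """Inverse of the projection walk: 1-based amino-acid index of a genomic
    base inside the CDS, or None when the base is non-coding."""
    offset = 0
    for block in _cds_walk(transcript):
        if block.start <= pos < block.end:
            if transcript.strand == "+":
                nt = offset + (pos - block.start)
            else:
                nt = offset + (block.end - 1 - pos)
            return nt // 3 + 1
        offset += block.length()
    return None


def build_domain_track(
    transcript: TranscriptModel,
    source,
    type_whitelist: set[str] | None = None,
    strict: bool = False,
) -> DomainTrack | None:
    """Assemble the domain track for one transcript, or None when no mapped
    protein passes CDS validation.

    When several protein IDs map to the transcript, the first whose CDS
    validation passes wins; the others are logged.
    """
    for pid in source.lookup_protein_ids(transcript.transcript_id):
        length, feats = source.fetch_features(pid, type_whitelist)
        if not validate_cds(transcript, length, strict=strict):
            log.info(
                "%s: protein %s (len %d aa) fails CDS validation "
                "(cds_length=%d), skipped",
                transcript.transcript_id, pid, length, transcript.cds_length(),
            )
            continue
        segments = []
        for f in feats:
            for seg in project_feature(transcript, f):
                segments.append((seg, f.description or f.feature_type))
        return DomainTrack(transcript.transcript_id, pid, segments)
    return None
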