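"""Detection of A-form promoter sequences (APS), motifs, and their coupling.

An APS is a maximal run of consecutive, determined, strictly negative APE
values of at least ``apelen`` positions, reported together with the two
flanking bases the triplet calculation requires.  A combined promoter
sequence (CPS) is an APS followed -- within at most ``motifgap`` bases -- by
an exact occurrence of a configured motif or its reverse complement; the CPS
spans from the start of the APS to the end of the motif.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np

from .ape import ApeProfile, ApeTable, BASES, ape_profile, revcomp

FORWARD = "forward"
REVCOMP = "reverse_complement"


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters.

    motifs : exact-string promoter motifs to search (with reverse complements)
    apelen : minimum number of consecutive negative APE values in an APS
    motifgap : maximum bases between the APS (incl. its 3' flank) and the motif
    genegap : size in bp of the upstream window scanned before each TSS
    """

    motifs: tuple[str, ...] = ("CCAAT",)
    apelen: int = 10
    motifgap: int = 20
    genegap: int = 500

    def __post_init__(self) -> None:
        norm = tuple(m.upper() for m in self.motifs)
        if not norm:
            raise ValueError("at least one motif is required")
        for m in norm:
            if not m or any(b not in BASES for b in m):
                raise ValueError(f"motif must be a non-empty ACGT string, got {m!r}")
        object.__setattr__(self, "motifs", norm)
        if self.apelen < 1:
            raise ValueError("apelen must be >= 1")
        if self.motifgap < 0:
            raise ValueError("motifgap must be >= 0")
        if self.genegap < 1:
            raise ValueError("genegap must be >= 1")


@dataclass(frozen=True)
class ApsHit:
    """A maximal negative-APE run plus its two flanking bases (0-based, inclusive)."""

    run_start: int
    run_end: int
    run_length: int
    span_start: int
    span_end: int
    min_ape: float
    sum_ape: float


@dataclass(frozen=True)
class MotifHit:
    """One exact motif occurrence (0-based, inclusive coordinates)."""

    start: int
    end: int
    matched_text: str
    orientation: str  # FORWARD or REVCOMP
    source_motif: str


@dataclass(frozen=True)
class CpsHit:
    """An (APS, motif) coupling; spans APS start to motif end."""

    aps: ApsHit
    motif: MotifHit
    gap: int
    cps_start: int
    cps_end: int


@dataclass(frozen=True)
class ScanResult:
    """Full output of :func:`scan_region`: CPS plus the underlying elements."""

    aps: tuple[ApsHit, ...]
    motifs: tuple[MotifHit, ...]
    cps: tuple[CpsHit, ...]
    profile: ApeProfile = field(repr=False, default=None)


def find_aps(profile: ApeProfile, apelen: int) -> list[ApsHit]:
    """All maximal runs of >= ``apelen`` consecutive negative APE positions.

    A run is broken by any undetermined position and by a value of exactly
    zero ("negative" is read strictly).  Runs are returned in ascending
    position order; nested sub-runs are never reported.
    """
    if apelen < 1:
        raise ValueError("apelen must be >= 1")
    with np.errstate(invalid="ignore"):
        neg = profile.determined & (profile.values < 0)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], neg.view(np.int8), [0]))))
    hits = []
    for s, e in zip(edges[0::2], edges[1::2]):  # run occupies [s, e)
        length = int(e - s)
        if length < apelen:
            continue
        vals = profile.values[s:e]
        hits.append(
            ApsHit(
                run_start=int(s),
                run_end=int(e - 1),
                run_length=length,
                span_start=int(s - 1),
                span_end=int(e),
                min_ape=float(vals.min()),
                sum_ape=float(vals.sum()),
            )
        )
    return hits


def find_motifs(sequence: str, motifs: list[str] | tuple[str, ...]) -> list[MotifHit]:
    """All occurrences of each motif and of its reverse complement.

    Case-insensitive; overlapping occurrences are all reported.  For a
    palindromic motif each position is reported once, as forward.  Sorted by
    start, then orientation, then source motif.
    """
    seq = sequence.upper()
    hits: list[MotifHit] = []
    for motif in motifs:
        m = motif.upper()
        patterns = [(m, FORWARD)]
        rc = revcomp(m)
        if rc != m:
            patterns.append((rc, REVCOMP))
        for pattern, orientation in patterns:
            start = seq.find(pattern)
            while start != -1:
                hits.append(
                    MotifHit(
                        start=start,
                        end=start + len(pattern) - 1,
                        matched_text=pattern,
                        orientation=orientation,
                        source_motif=m,
                    )
                )
                start = seq.find(pattern, start + 1)
    hits.sort(key=lambda h: (h.start, h.orientation != FORWARD, h.source_motif))
    return hits


def find_cps(
    aps_hits: list[ApsHit], motif_hits: list[MotifHit], motifgap: int
) -> list[CpsHit]:
    """Couple APS and motif hits: motif strictly downstream, gap <= motifgap.

    ``gap`` counts the bases strictly between the APS span end (which
    includes the 3' flanking base) and the motif start.  Every qualifying
    (APS, motif) pair yields its own :class:`CpsHit`.
    """
    if motifgap < 0:
        raise ValueError("motifgap must be >= 0")
    starts = [m.start for m in motif_hits]
    order = sorted(range(len(motif_hits)), key=lambda i: starts[i])
    sorted_starts = [starts[i] for i in order]
    out: list[CpsHit] = []
    for aps in sorted(aps_hits, key=lambda a: a.run_start):
        lo = bisect_left(sorted_starts, aps.span_end + 1)
        hi = bisect_right(sorted_starts, aps.span_end + 1 + motifgap)
        window = sorted(
            (motif_hits[order[i]] for i in range(lo, hi)),
            key=lambda m: (m.start, m.orientation != FORWARD, m.source_motif),
        )
        for motif in window:
            out.append(
                CpsHit(
                    aps=aps,
                    motif=motif,
                    gap=motif.start - aps.span_end - 1,
                    cps_start=aps.span_start,
                    cps_end=motif.end,
                )
            )
    return out


def scan_region(sequence: str, table: ApeTable, config: ScanConfig) -> ScanResult:
    """Full scan of one oriented sequence: profile -> APS -> motifs -> CPS."""
    profile = ape_profile(table, sequence)
    aps = find_aps(profile, config.apelen)
    motifs = find_motifs(profile.sequence, config.motifs)
    cps = find_cps(aps, motifs, config.motifgap)
    return ScanResult(
        aps=tuple(aps), motifs=tuple(motifs), cps=tuple(cps), profile=profile
    )
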