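"""Serialisation of scan results: TSV results table, BED, WIG and GFF3 tracks.

Coordinate conventions follow the formats themselves: the TSV and GFF3 use
1-based inclusive genomic intervals, BED is 0-based half-open, and WIG
fixedStep positions are 1-based.  For every interval, BED start equals the
GFF3 start minus one and the BED end equals the GFF3 end.  All writers are
deterministic byte-for-byte given identical inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import UpstreamRegion, hits_to_genome, tss
from .scanner import ScanResult
from .ape import ApeProfile

#: Stable column layout of the results table (one row per CPS).
RESULT_COLUMNS = (
    "gene_id",
    "gene_name",
    "seqid",
    "strand",
    "tss",
    "aps_start",
    "aps_end",
    "aps_run_length",
    "motif_start",
    "motif_end",
    "motif_text",
    "motif_orientation",
    "gap",
    "cps_start",
    "cps_end",
)


@dataclass(frozen=True)
class ResultRow:
    """One combined promoter sequence in genomic coordinates (1-based incl.).

    ``aps_start``/``aps_end`` cover the flanked APS span; the motif
    orientation is reported relative to the gene-sense scanned strand.
    """

    gene_id: str
    gene_name: str | None
    seqid: str
    strand: str
    tss: int
    aps_start: int
    aps_end: int
    aps_run_length: int
    motif_start: int
    motif_end: int
    motif_text: str
    motif_orientation: str
    gap: int
    cps_start: int
    cps_end: int


assert tuple(f.name for f in fields(ResultRow)) == RESULT_COLUMNS


def rows_for_gene(region: UpstreamRegion, result: ScanResult) -> list[ResultRow]:
    """Build one :class:`ResultRow` per CPS found in a gene's window."""
    gene = region.gene
    rows = []
    for cps in result.cps:
        aps_g = region.interval_to_genomic(cps.aps.span_start, cps.aps.span_end)
        motif_g = region.interval_to_genomic(cps.motif.start, cps.motif.end)
        cps_g = region.interval_to_genomic(cps.cps_start, cps.cps_end)
        rows.append(
            ResultRow(
                gene_id=gene.gene_id,
                gene_name=gene.gene_name,
                seqid=gene.seqid,
                strand=gene.strand,
                tss=tss(gene),
                aps_start=aps_g[0],
                aps_end=aps_g[1],
                aps_run_length=cps.aps.run_length,
                motif_start=motif_g[0],
                motif_end=motif_g[1],
                motif_text=cps.motif.matched_text,
                motif_orientation=cps.motif.orientation,
                gap=cps.gap,
                cps_start=cps_g[0],
                cps_end=cps_g[1],
            )
        )
    return rows


def _row_sort_key(row: ResultRow):
    return (row.seqid, row.tss, row.cps_start, row.cps_end, row.motif_start)


def write_results_tsv(rows: Iterable[ResultRow], path: str | Path) -> None:
    """Write the results table: header plus one tab-separated line per CPS."""
    ordered = sorted(rows, key=_row_sort_key)
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for row in ordered:
            values = [getattr(row, col) for col in RESULT_COLUMNS]
            fh.write("\t".join("." if v is None else str(v) for v in values) + "\n")


# ---------------------------------------------------------------------------
# BED

def ape_sign_segments(
    region: UpstreamRegion, profile: ApeProfile
) -> list[tuple[str, int, int, str]]:
    """Segment a window by APE sign: (seqid, start1, end1, label) tiles.

    Labels are ``neg`` (value < 0), ``pos`` (value >= 0) and ``undet``;
    adjacent equal labels merge, so the tiles cover the region exactly once
    in ascending genomic order.
    """
    n = len(profile)
    if n == 0:
        return []
    det = profile.determined
    vals = profile.values
    if region.direction == -1:  # genomic-ascending view of the oriented profile
        det, vals = det[::-1], vals[::-1]
    with np.errstate(invalid="ignore"):
        labels = np.where(~det, "undet", np.where(vals < 0, "neg", "pos"))
    lo = min(region.genomic_start, region.genomic_end)
    segments = []
    seg_start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[seg_start]:
            segments.append(
                (region.gene.seqid, lo + seg_start, lo + i - 1, str(labels[seg_start]))
            )
            seg_start = i
    return segments


def write_bed(
    path: str | Path,
    aps_intervals: Sequence[tuple[str, int, int, str]],
    motif_intervals: Sequence[tuple[str, int, int, str]],
    sign_segments: Sequence[tuple[str, int, int, str]],
) -> None:
    """Write the three annotation tracks as one BED file.

    Inputs are (seqid, start, end, name) with 1-based inclusive coordinates;
    they are emitted 0-based half-open under ``track`` lines named ``aps``,
    ``motif`` and ``ape_sign``.
    """
    tracks = (
        ("aps", "A-form promoter sequences (flanked spans)", aps_intervals),
        ("motif", "promoter motif occurrences", motif_intervals),
        ("ape_sign", "sign of the APE values over the search regions", sign_segments),
    )
    with open(path, "w") as fh:
        for name, description, intervals in tracks:
            fh.write(f'track name={name} description="{description}"\n')
            for seqid, start, end, label in sorted(intervals):
                fh.write(f"{seqid}\t{start - 1}\t{end}\t{label}\n")


def bed_tracks_for_gene(
    region: UpstreamRegion, result: ScanResult
) -> tuple[list, list, list]:
    """Genomic (seqid, start1, end1, name) tuples for one gene's three tracks."""
    gene = region.gene
    aps_iv = [
        (f.seqid, f.start, f.end, f"{gene.gene_id}_APS")
        for f in hits_to_genome(region, result.aps)
    ]
    motif_iv = [
        (f.seqid, f.start, f.end, f"{gene.gene_id}_{f.hit.matched_text}")
        for f in hits_to_genome(region, result.motifs)
    ]
    signs = ape_sign_segments(region, result.profile)
    return aps_iv, motif_iv, signs


# ---------------------------------------------------------------------------
# WIG

def wig_blocks(
    region: UpstreamRegion, profile: ApeProfile
) -> list[tuple[int, list[float]]]:
    """FixedStep blocks (1-based genomic start, values) of determined APE runs.

    Undetermined positions are omitted entirely, breaking the track into
    multiple blocks; values are emitted in ascending genomic order (the APE
    sum is strand-symmetric, so orientation does not change them).
    """
    n = len(profile)
    if n == 0:
        return []
    det = profile.determined
    vals = profile.values
    if region.direction == -1:
        det, vals = det[::-1], vals[::-1]
    lo = min(region.genomic_start, region.genomic_end)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], det.view(np.int8), [0]))))
    return [
        (lo + int(s), [float(v) for v in vals[s:e]])
        for s, e in zip(edges[0::2], edges[1::2])
    ]


def write_wig(
    path: str | Path,
    region_profiles: Iterable[tuple[UpstreamRegion, ApeProfile]],
    track_name: str = "ape",
) -> None:
    """Write APE scores as a wiggle track (fixedStep, step=1, span=1)."""
    entries = []
    for region, profile in region_profiles:
        for start, values in wig_blocks(region, profile):
            entries.append((region.gene.seqid, start, values))
    with open(path, "w") as fh:
        fh.write(
            f'track type=wiggle_0 name={track_name} '
            f'description="A-DNA propensity energy (kcal/mol)"\n'
        )
        for seqid, start, values in sorted(entries, key=lambda e: (e[0], e[1])):
            fh.write(f"fixedStep chrom={seqid} start={start} step=1 span=1\n")
            for v in values:
                fh.write(f"{v:.6g}\n")


# ---------------------------------------------------------------------------
# GFF3

def write_gff(rows: Iterable[ResultRow], path: str | Path) -> None:
    """Write results as GFF3: one CPS feature with APS and motif children."""
    ordered = sorted(rows, key=_row_sort_key)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, row in enumerate(ordered, start=1):
            cid = f"cps{i:05d}"
            strand = row.strand
            fh.write(
                f"{row.seqid}\taformscan\tCPS\t{row.cps_start}\t{row.cps_end}\t.\t"
                f"{strand}\t.\tID={cid};gene_id={row.gene_id};gap={row.gap}\n"
            )
            fh.write(
                f"{row.seqid}\taformscan\tAPS\t{row.aps_start}\t{row.aps_end}\t.\t"
                f"{strand}\t.\tID={cid}.aps;Parent={cid};gene_id={row.gene_id};"
                f"run_length={row.aps_run_length}\n"
            )
            fh.write(
                f"{row.seqid}\taformscan\tmotif\t{row.motif_start}\t{row.motif_end}"
                f"\t.\t{strand}\t.\tID={cid}.motif;Parent={cid};"
                f"gene_id={row.gene_id};orientation={row.motif_orientation};"
                f"matched_text={row.motif_text}\n"
            )
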