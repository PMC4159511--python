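"""Synthetic genomes with planted A-form elements, plus synthetic APE tables.

The generator emits FASTA + GFF3 + an exact truth table so the whole scan
pipeline is testable without any external assembly.  Planted A-form runs
are guanine tracts on the gene-sense strand (the field's canonical A-philic
sequence); minus-strand genes exercise the reverse-complement path, turning
them into C tracts on the reference strand.  Background sequence around a
plant is resampled until it can neither create an unplanned G/C run long
enough to be an APS nor drop a guard motif into the coupling window, so the
truth table is exact by construction -- the scanner itself is never
consulted while generating.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ape import ALL_TRIPLETS, ApeTable, BASES, revcomp
from .genome import GeneRecord, UpstreamRegion, tss, upstream_region
from .nullmodel import XTROP_FREQUENCIES, _normalized_frequencies
from .scanner import FORWARD, REVCOMP

TRUTH_COLUMNS = (
    "gene_id",
    "gene_name",
    "seqid",
    "strand",
    "tss",
    "kind",
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

#: Motifs whose chance occurrence near a plant is rejected during generation.
GUARD_MOTIFS = ("CCAAT", "GGGCGG", "AGATA", "TGATA")


class SynthesisError(ValueError):
    """Raised when a plant cannot fit its window or generation fails."""


@dataclass(frozen=True)
class Plant:
    """Per-gene plant directive.

    kind : "aps" (structural element only) or "cps" (element + motif)
    offset_from_tss : oriented bases between the plant's 3' end and the TSS
    """

    kind: str = "cps"
    motif: str = "CCAAT"
    gap: int = 5
    run_length: int = 12
    orientation: str = FORWARD
    offset_from_tss: int = 40

    def __post_init__(self) -> None:
        if self.kind not in ("aps", "cps"):
            raise SynthesisError(f"unknown plant kind {self.kind!r}")
        if self.orientation not in (FORWARD, REVCOMP):
            raise SynthesisError(f"unknown orientation {self.orientation!r}")
        if self.gap < 0 or self.run_length < 1 or self.offset_from_tss < 1:
            raise SynthesisError("gap/run_length/offset_from_tss out of range")


@dataclass(frozen=True)
class PlantSpec:
    """Blueprint for one synthetic genome."""

    n_genes: int
    genegap: int = 500
    apelen: int = 10
    motifgap: int = 20
    frequencies: tuple = XTROP_FREQUENCIES
    plants: Sequence[Plant | None] | None = None  # per gene; None -> no plant
    strands: Sequence[str] | None = None  # per gene; default alternates +/-
    gene_body: int = 200
    seqid: str = "chrS"
    seed: int = 0
    max_tries: int = 500


@dataclass(frozen=True)
class SyntheticGenome:
    """In-memory genome: contigs, gene records and the plant truth table."""

    contigs: dict[str, str]
    genes: list[GeneRecord]
    truth: pd.DataFrame
    spec: PlantSpec = field(repr=False, default=None)


def _plant_layout(plant: Plant, window: int) -> dict[str, int]:
    """Oriented coordinates of a plant inside a window of ``window`` bases."""
    if plant.kind == "cps":
        motif_end = window - 1 - plant.offset_from_tss
        motif_start = motif_end - len(plant.motif) + 1
        span_end = motif_start - plant.gap - 1
    else:
        motif_end = motif_start = -1
        span_end = window - 1 - plant.offset_from_tss
    run_end = span_end - 1
    run_start = run_end - plant.run_length + 1
    span_start = run_start - 1
    if span_start < 2 or (plant.kind == "cps" and motif_end > window - 2):
        raise SynthesisError(
            f"plant does not fit a {window}-base window: span {span_start}..; "
            f"leave at least 2 bases of margin"
        )
    return {
        "run_start": run_start,
        "run_end": run_end,
        "span_start": span_start,
        "span_end": span_end,
        "motif_start": motif_start,
        "motif_end": motif_end,
    }


def _gc_runs(window: str, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of G/C bases with length >= min_len (0-based inclusive)."""
    runs = []
    start = None
    for i, b in enumerate(window + "$"):
        if b in "GC":
            if start is None:
                start = i
        elif start is not None:
            if i - start >= min_len:
                runs.append((start, i - 1))
            start = None
    return runs


def _motif_starts(window: str, motifs: Sequence[str]) -> set[int]:
    starts = set()
    for motif in motifs:
        for pattern in {motif.upper(), revcomp(motif.upper())}:
            i = window.find(pattern)
            while i != -1:
                starts.add(i)
                i = window.find(pattern, i + 1)
    return starts


def _random_window(freqs_cum: np.ndarray, n: int, rng: np.random.Generator) -> list[str]:
    u = rng.random(n)
    codes = np.searchsorted(freqs_cum, u, side="right")
    return [BASES[c] for c in codes]


def _build_window(
    plant: Plant | None, spec: PlantSpec, freqs_cum: np.ndarray, rng
) -> tuple[str, dict | None]:
    """Generate one oriented upstream window honouring the plant directive."""
    W = spec.genegap
    layout = _plant_layout(plant, W) if plant is not None else None
    if plant is not None and plant.run_length < spec.apelen:
        raise SynthesisError("planted run_length must be >= apelen to be an APS")
    guard = set(GUARD_MOTIFS)
    if plant is not None and plant.kind == "cps":
        guard.add(plant.motif.upper())
    for _ in range(spec.max_tries):
        chars = _random_window(freqs_cum, W, rng)
        if layout is not None:
            # T/A guards pin the run to exactly the planted interval
            chars[layout["span_start"] - 1] = "T"
            chars[layout["span_start"]] = "A"
            for p in range(layout["run_start"], layout["run_end"] + 1):
                chars[p] = "G"
            chars[layout["span_end"]] = "A"
            if layout["span_end"] + 1 < W:
                chars[layout["span_end"] + 1] = "T"
            if plant.kind == "cps":
                text = (
                    plant.motif.upper()
                    if plant.orientation == FORWARD
                    else revcomp(plant.motif.upper())
                )
                for k, b in enumerate(text):
                    chars[layout["motif_start"] + k] = b
        window = "".join(chars)
        runs = _gc_runs(window, spec.apelen)
        expected_runs = (
            [(layout["run_start"], layout["run_end"])] if layout is not None else []
        )
        if runs != expected_runs:
            continue
        if layout is not None:
            coupling = {
                s
                for s in _motif_starts(window, tuple(guard))
                if layout["span_end"] + 1 <= s <= layout["span_end"] + 1 + spec.motifgap
            }
            planted = {layout["motif_start"]} if plant.kind == "cps" else set()
            if coupling != planted:
                continue
        return window, layout
    raise SynthesisError(
        f"could not generate a clean window in {spec.max_tries} tries"
    )


def build_synthetic_genome(spec: PlantSpec) -> SyntheticGenome:
    """Generate a deterministic synthetic genome from a :class:`PlantSpec`."""
    if spec.n_genes < 0:
        raise SynthesisError("n_genes must be >= 0")
    plants = list(spec.plants) if spec.plants is not None else [None] * spec.n_genes
    if len(plants) != spec.n_genes:
        raise SynthesisError("plants must have one entry per gene")
    strands = (
        list(spec.strands)
        if spec.strands is not None
        else [("+", "-")[i % 2] for i in range(spec.n_genes)]
    )
    if len(strands) != spec.n_genes:
        raise SynthesisError("strands must have one entry per gene")
    freqs_cum = np.cumsum(_normalized_frequencies(spec.frequencies))
    freqs_cum[-1] = 1.0
    rng = np.random.default_rng(spec.seed)

    slot = 2 * spec.genegap + spec.gene_body + 10
    contig_len = max(spec.n_genes * slot + 100, 200)
    contig = _random_window(freqs_cum, contig_len, rng)

    genes: list[GeneRecord] = []
    windows: list[tuple[GeneRecord, str, dict | None, Plant | None]] = []
    for i in range(spec.n_genes):
        slot_start = 1 + i * slot
        body_start = slot_start + spec.genegap
        body_end = body_start + spec.gene_body - 1
        gene = GeneRecord(
            gene_id=f"g{i + 1:03d}",
            gene_name=f"synthg{i + 1:03d}",
            seqid=spec.seqid,
            start=body_start,
            end=body_end,
            strand=strands[i],
        )
        window, layout = _build_window(plants[i], spec, freqs_cum, rng)
        if gene.strand == "+":
            gs = body_start - spec.genegap
            contig[gs - 1 : gs - 1 + spec.genegap] = list(window)
        else:
            gs = body_end + 1
            contig[gs - 1 : gs - 1 + spec.genegap] = list(revcomp(window))
        genes.append(gene)
        windows.append((gene, window, layout, plants[i]))

    contigs = {spec.seqid: "".join(contig)}
    truth_rows = []
    for gene, window, layout, plant in windows:
        if layout is None:
            continue
        region = upstream_region(gene, spec.genegap, contigs)
        assert region.oriented_sequence == window  # construction invariant
        aps_g = region.interval_to_genomic(layout["span_start"], layout["span_end"])
        row = {
            "gene_id": gene.gene_id,
            "gene_name": gene.gene_name,
            "seqid": gene.seqid,
            "strand": gene.strand,
            "tss": tss(gene),
            "kind": plant.kind,
            "aps_start": aps_g[0],
            "aps_end": aps_g[1],
            "aps_run_length": plant.run_length,
            "motif_start": pd.NA,
            "motif_end": pd.NA,
            "motif_text": pd.NA,
            "motif_orientation": pd.NA,
            "gap": pd.NA,
            "cps_start": pd.NA,
            "cps_end": pd.NA,
        }
        if plant.kind == "cps":
            motif_g = region.interval_to_genomic(
                layout["motif_start"], layout["motif_end"]
            )
            cps_g = region.interval_to_genomic(
                layout["span_start"], layout["motif_end"]
            )
            text = (
                plant.motif.upper()
                if plant.orientation == FORWARD
                else revcomp(plant.motif.upper())
            )
            row.update(
                motif_start=motif_g[0],
                motif_end=motif_g[1],
                motif_text=text,
                motif_orientation=plant.orientation,
                gap=plant.gap,
                cps_start=cps_g[0],
                cps_end=cps_g[1],
            )
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    return SyntheticGenome(contigs=contigs, genes=genes, truth=truth, spec=spec)


def make_synthetic_genome(
    spec: PlantSpec, outdir: str | Path
) -> tuple[Path, Path, Path, SyntheticGenome]:
    """Generate a synthetic genome and write FASTA + GFF3 + truth TSV files."""
    genome = build_synthetic_genome(spec)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_path = outdir / "genome.fa"
    gff3_path = outdir / "genes.gff3"
    truth_path = outdir / "truth.tsv"
    with open(fasta_path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in genome.contigs.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for gene in genome.genes:
            fh.write(
                f"{gene.seqid}\tsynth\tgene\t{gene.start}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id};Name={gene.gene_name}\n"
            )
    genome.truth.to_csv(truth_path, sep="\t", index=False, na_rep=".")
    return fasta_path, gff3_path, truth_path, genome


def make_test_ape_table(kind: str, seed: int | None = None) -> ApeTable:
    """Synthetic APE tables for algorithm tests.

    uniform_negative
        every triplet -1.0 per strand (all pair values -2.0)
    gc_negative
        -1.0 when the central base is G or C, else +1.0; pair sums then
        track the central base, so APS runs coincide with G/C tracts
    random
        seeded values in [-2, 2] with 14 random undetermined triplets,
        mirroring the shape of the real energy table
    """
    if kind == "uniform_negative":
        return ApeTable({t: -1.0 for t in ALL_TRIPLETS}, source_name="synthetic:uniform_negative")
    if kind == "gc_negative":
        return ApeTable(
            {t: (-1.0 if t[1] in "GC" else 1.0) for t in ALL_TRIPLETS},
            source_name="synthetic:gc_negative",
        )
    if kind == "random":
        rng = np.random.default_rng(seed)
        values = rng.uniform(-2.0, 2.0, size=64).round(4)
        undet = set(rng.choice(64, size=14, replace=False).tolist())
        entries = {
            t: float(values[i]) for i, t in enumerate(ALL_TRIPLETS) if i not in undet
        }
        return ApeTable(entries, source_name=f"synthetic:random:{seed}")
    raise ValueError(f"unknown table kind {kind!r}")
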