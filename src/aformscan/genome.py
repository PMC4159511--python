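"""Genome and annotation access: FASTA + GFF3 in, oriented upstream windows out.

Genes come from GFF3 (1-based, inclusive).  The transcription start site
(TSS) is taken as the 5' end of the gene feature; the scanned window is the
``genegap`` bases strictly upstream of it, read in the gene's 5'->3' sense
(reverse-complemented for minus-strand genes) and clipped at contig edges.
Scan hits on the oriented window map back to genomic coordinates through an
affine anchor+direction offset map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gffutils

from .ape import ApeTable, revcomp
from .scanner import ApsHit, CpsHit, MotifHit, ScanConfig, ScanResult, scan_region

logger = logging.getLogger(__name__)


class Gff3FormatError(ValueError):
    """Raised for a GFF3 line that cannot be parsed; names the line number."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene feature (1-based inclusive genomic coordinates)."""

    gene_id: str
    gene_name: str | None
    seqid: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid coordinates {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class UpstreamRegion:
    """The oriented upstream window of a gene.

    ``oriented_sequence`` runs 5'->3' in the gene sense: oriented position 0
    is the base farthest from the TSS, the last position is adjacent to it.
    ``anchor``/``direction`` form the affine map oriented->genomic:
    genomic = anchor + direction * oriented.
    """

    gene: GeneRecord
    genomic_start: int  # 1-based inclusive; start > end encodes an empty window
    genomic_end: int
    oriented_sequence: str
    anchor: int
    direction: int  # +1 for plus-strand genes, -1 for minus-strand

    def __len__(self) -> int:
        return len(self.oriented_sequence)

    def to_genomic(self, oriented_pos: int) -> int:
        """Map a 0-based oriented position to a 1-based genomic coordinate."""
        if not 0 <= oriented_pos < len(self):
            raise ValueError(f"oriented position {oriented_pos} outside region")
        return self.anchor + self.direction * oriented_pos

    def to_oriented(self, genomic_pos: int) -> int:
        """Inverse of :meth:`to_genomic`."""
        p = (genomic_pos - self.anchor) * self.direction
        if not 0 <= p < len(self):
            raise ValueError(f"genomic position {genomic_pos} outside region")
        return p

    def interval_to_genomic(self, start: int, end: int) -> tuple[int, int]:
        """Map an oriented [start, end] interval to an ascending genomic one."""
        a, b = self.to_genomic(start), self.to_genomic(end)
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class GenomicFeature:
    """A scan hit lifted to genomic coordinates (1-based inclusive)."""

    seqid: str
    start: int
    end: int
    kind: str  # "APS" | "motif" | "CPS"
    gene_strand: str
    oriented_start: int
    oriented_end: int
    hit: object


def read_genes(
    gff3_path: str | Path,
    feature_type: str = "gene",
    id_attr: str = "ID",
    name_attr: str = "Name",
) -> list[GeneRecord]:
    """Read gene records from a GFF3 file.

    Only features of ``feature_type`` are returned; ``gene_id`` comes from
    the ``ID`` attribute and ``gene_name`` from ``Name`` when present.
    Features lacking the ID attribute or a +/- strand are skipped with a
    warning.  A structurally unparseable line raises
    :class:`Gff3FormatError` naming the line number.
    """
    gff3_path = Path(gff3_path)
    with open(gff3_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise Gff3FormatError(
                    f"{gff3_path}:{lineno}: expected 9 tab-separated fields"
                )
    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    genes: list[GeneRecord] = []
    for feat in db.features_of_type(feature_type):
        if id_attr not in feat.attributes:
            logger.warning(
                "skipping %s feature at %s:%d-%d: no %s attribute",
                feature_type, feat.seqid, feat.start, feat.end, id_attr,
            )
            continue
        if feat.strand not in "+-":
            logger.warning(
                "skipping %s %s: strand %r is not +/-",
                feature_type, feat.attributes[id_attr][0], feat.strand,
            )
            continue
        name = feat.attributes[name_attr][0] if name_attr in feat.attributes else None
        genes.append(
            GeneRecord(
                gene_id=feat.attributes[id_attr][0],
                gene_name=name,
                seqid=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
            )
        )
    genes.sort(key=lambda g: (g.seqid, g.start, g.end, g.gene_id))
    return genes


def tss(gene: GeneRecord) -> int:
    """Transcription start site: the 5' end of the gene feature (1-based)."""
    return gene.start if gene.strand == "+" else gene.end


def upstream_region(
    gene: GeneRecord, genegap: int, genome: Mapping[str, object]
) -> UpstreamRegion:
    """Extract the ``genegap``-bp window strictly upstream of the gene's TSS.

    ``genome`` may be a ``pyfaidx.Fasta`` or any mapping of contig name to
    sequence.  The window excludes the TSS base itself, is clipped at contig
    edges, and is reverse-complemented for minus-strand genes so that the
    returned sequence reads 5'->3' toward the gene.
    """
    if genegap < 1:
        raise ValueError("genegap must be >= 1")
    try:
        contig = genome[gene.seqid]
    except KeyError:
        raise KeyError(f"contig {gene.seqid!r} not present in genome") from None
    contig_length = len(contig)
    if gene.strand == "+":
        gstart = max(1, gene.start - genegap)
        gend = gene.start - 1
        anchor, direction = gstart, 1
    else:
        gstart = gene.end + 1
        gend = min(contig_length, gene.end + genegap)
        anchor, direction = gend, -1
    if gend < gstart:  # TSS at the contig edge: empty window
        return UpstreamRegion(gene, gstart, gend, "", anchor, direction)
    seq = str(contig[gstart - 1 : gend]).upper()
    if gene.strand == "-":
        seq = revcomp(seq)
    return UpstreamRegion(gene, gstart, gend, seq, anchor, direction)


def hits_to_genome(
    region: UpstreamRegion, hits: Iterable[ApsHit | MotifHit | CpsHit]
) -> list[GenomicFeature]:
    """Map oriented-coordinate scan hits back to genomic coordinates.

    APS hits map their flanked span, motif hits their match, CPS hits their
    full extent.  Genomic ``start <= end`` always holds; the original
    oriented coordinates travel along for reporting.
    """
    out: list[GenomicFeature] = []
    for hit in hits:
        if isinstance(hit, ApsHit):
            o_start, o_end, kind = hit.span_start, hit.span_end, "APS"
        elif isinstance(hit, MotifHit):
            o_start, o_end, kind = hit.start, hit.end, "motif"
        elif isinstance(hit, CpsHit):
            o_start, o_end, kind = hit.cps_start, hit.cps_end, "CPS"
        else:
            raise TypeError(f"cannot map hit of type {type(hit).__name__}")
        g_start, g_end = region.interval_to_genomic(o_start, o_end)
        out.append(
            GenomicFeature(
                seqid=region.gene.seqid,
                start=g_start,
                end=g_end,
                kind=kind,
                gene_strand=region.gene.strand,
                oriented_start=o_start,
                oriented_end=o_end,
                hit=hit,
            )
        )
    return out


def scan_gene(
    gene: GeneRecord,
    genome: Mapping[str, object],
    table: ApeTable,
    config: ScanConfig,
) -> tuple[UpstreamRegion, ScanResult]:
    """Scan one gene's oriented upstream window."""
    region = upstream_region(gene, config.genegap, genome)
    return region, scan_region(region.oriented_sequence, table, config)


def scan_genes(
    genes: Iterable[GeneRecord],
    genome: Mapping[str, object],
    table: ApeTable,
    config: ScanConfig,
) -> Iterator[tuple[GeneRecord, UpstreamRegion, ScanResult]]:
    """Scan many genes; yields (gene, region, result) per gene."""
    for gene in genes:
        region, result = scan_gene(gene, genome, table, config)
        yield gene, region, result
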