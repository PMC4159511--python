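"""Round-trip and convention tests for the TSV/BED/WIG/GFF3 writers."""

import numpy as np
import pytest

from aformscan import (
    ApeProfile,
    GeneRecord,
    Plant,
    PlantSpec,
    ScanConfig,
    ape_profile,
    build_synthetic_genome,
    read_genes,
    rows_for_gene,
    scan_genes,
    upstream_region,
    write_bed,
    write_gff,
    write_results_tsv,
    write_wig,
)
from aformscan.trackio import (
    RESULT_COLUMNS,
    ResultRow,
    ape_sign_segments,
    bed_tracks_for_gene,
    wig_blocks,
)

from oracles import random_dna


def parse_bed(path):
    tracks = {}
    current = None
    for line in path.read_text().splitlines():
        if line.startswith("track name="):
            current = line.split()[1].split("=")[1]
            tracks[current] = []
        else:
            chrom, start, end, name = line.split("\t")
            tracks[current].append((chrom, int(start), int(end), name))
    return tracks


def parse_wig(path):
    blocks = []
    chrom = start = None
    values = []
    for line in path.read_text().splitlines():
        if line.startswith("track"):
            continue
        if line.startswith("fixedStep"):
            if values:
                blocks.append((chrom, start, values))
            fields = dict(f.split("=") for f in line.split()[1:])
            chrom, start, values = fields["chrom"], int(fields["start"]), []
        else:
            values.append(float(line))
    if values:
        blocks.append((chrom, start, values))
    return blocks


def make_row(**overrides):
    base = dict(
        gene_id="g1", gene_name="gdi3", seqid="chr1", strand="+", tss=1001,
        aps_start=501, aps_end=514, aps_run_length=12, motif_start=520,
        motif_end=524, motif_text="CCAAT", motif_orientation="forward",
        gap=5, cps_start=501, cps_end=524,
    )
    base.update(overrides)
    return ResultRow(**base)


@pytest.fixture()
def planted_scan(gc_table):
    """One planted CPS per strand, scanned, with regions and rows."""
    spec = PlantSpec(
        n_genes=2, genegap=200, plants=[Plant(), Plant()], seed=6,
    )
    genome = build_synthetic_genome(spec)
    config = ScanConfig(apelen=10, motifgap=20, genegap=200)
    out = list(scan_genes(genome.genes, genome.contigs, gc_table, config))
    return genome, out


class TestResultsTsv:
    def test_zero_rows_header_only(self, tmp_path):
        path = tmp_path / "r.tsv"
        write_results_tsv([], path)
        assert path.read_text() == "\t".join(RESULT_COLUMNS) + "\n"

    def test_planted_cps_row_matches_truth(self, tmp_path, planted_scan):
        genome, scans = planted_scan
        rows = [r for _, region, result in scans for r in rows_for_gene(region, result)]
        path = tmp_path / "r.tsv"
        write_results_tsv(rows, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 + len(genome.truth)
        for line, truth in zip(lines[1:], genome.truth.itertuples()):
            fields = dict(zip(RESULT_COLUMNS, line.split("\t")))
            assert int(fields["aps_start"]) == truth.aps_start
            assert int(fields["cps_end"]) == truth.cps_end
            assert fields["motif_text"] == truth.motif_text

    def test_multiple_cps_per_gene_stable_order(self, tmp_path):
        rows = [
            make_row(motif_start=540, motif_end=544, cps_end=544),
            make_row(),
        ]
        path_a, path_b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_results_tsv(rows, path_a)
        write_results_tsv(list(reversed(rows)), path_b)
        assert path_a.read_bytes() == path_b.read_bytes()
        ends = [line.split("\t")[-1] for line in path_a.read_text().splitlines()[1:]]
        assert ends == ["524", "544"]


class TestBed:
    def test_half_open_convention(self, tmp_path):
        path = tmp_path / "t.bed"
        write_bed(path, [("chr1", 501, 1000, "x")], [], [])
        tracks = parse_bed(path)
        assert tracks["aps"] == [("chr1", 500, 1000, "x")]

    def test_sign_segments_tile_region(self, rng, gc_table):
        seq = "N" + "G" * 12 + "N" + random_dna(rng, 6)
        contig = {"c": seq + "A" * 40}
        gene = GeneRecord("g", None, "c", len(seq) + 1, len(seq) + 30, "+")
        region = upstream_region(gene, len(seq), contig)
        profile = ape_profile(gc_table, region.oriented_sequence)
        segments = ape_sign_segments(region, profile)
        # adjacent, non-overlapping, covering the region exactly
        assert segments[0][1] == region.genomic_start
        assert segments[-1][2] == region.genomic_end
        for left, right in zip(segments, segments[1:]):
            assert right[1] == left[2] + 1
        labels = {s[3] for s in segments}
        assert labels <= {"neg", "pos", "undet"}
        assert "neg" in labels

    def test_round_trip_random_hits(self, tmp_path, rng):
        intervals = sorted(
            ("chr%d" % rng.integers(1, 3), int(s), int(s) + int(rng.integers(1, 30)),
             f"h{i}")
            for i, s in enumerate(rng.integers(1, 5000, size=25))
        )
        path = tmp_path / "t.bed"
        write_bed(path, intervals, [], [])
        parsed = parse_bed(path)["aps"]
        restored = sorted((c, s + 1, e, n) for c, s, e, n in parsed)
        assert restored == intervals

    def test_byte_determinism(self, tmp_path, planted_scan):
        _, scans = planted_scan
        outputs = []
        for name in ("a.bed", "b.bed"):
            aps_iv, motif_iv, signs = [], [], []
            for _, region, result in scans:
                a, m, s = bed_tracks_for_gene(region, result)
                aps_iv += a
                motif_iv += m
                signs += s
            path = tmp_path / name
            write_bed(path, aps_iv, motif_iv, signs)
            outputs.append(path.read_bytes())
        assert outputs[0] == outputs[1]


class TestWig:
    def region(self, strand="+", length=500):
        contig = {"c": "A" * 2000}
        gene = (
            GeneRecord("g", None, "c", 1001, 1500, "+")
            if strand == "+"
            else GeneRecord("g", None, "c", 1, 500, "-")
        )
        return upstream_region(gene, length, contig)

    def test_all_undetermined_profile_writes_no_data(self, tmp_path):
        region = self.region()
        profile = ApeProfile(
            region.oriented_sequence,
            np.full(len(region), np.nan),
            np.zeros(len(region), dtype=bool),
        )
        path = tmp_path / "t.wig"
        write_wig(path, [(region, profile)])
        assert "fixedStep" not in path.read_text()

    def test_uniform_profile_single_block(self, tmp_path, uniform_table):
        region = self.region()  # genomic [501, 1000]
        profile = ape_profile(uniform_table, region.oriented_sequence)
        path = tmp_path / "t.wig"
        write_wig(path, [(region, profile)])
        ((chrom, start, values),) = parse_wig(path)
        assert (chrom, start) == ("c", 502)  # ends are undetermined
        assert len(values) == 498
        assert set(values) == {-2.0}

    def test_round_trip_random_profiles(self, tmp_path, rng):
        from aformscan import make_test_ape_table

        table = make_test_ape_table("random", seed=21)
        for strand in "+-":
            region = self.region(strand=strand, length=80)
            seq = random_dna(rng, 80)
            region = type(region)(
                gene=region.gene, genomic_start=region.genomic_start,
                genomic_end=region.genomic_end, oriented_sequence=seq,
                anchor=region.anchor, direction=region.direction,
            )
            profile = ape_profile(table, seq)
            path = tmp_path / f"t{strand}.wig"
            write_wig(path, [(region, profile)])
            restored = {}
            for chrom, start, values in parse_wig(path):
                for k, v in enumerate(values):
                    restored[start + k] = v
            expected = {}
            for pos in range(len(region)):
                if profile.determined[pos]:
                    expected[region.to_genomic(pos)] = profile.values[pos]
            assert set(restored) == set(expected)
            for g, v in expected.items():
                assert restored[g] == pytest.approx(v, abs=1e-6)


class TestGff:
    def test_zero_rows_pragma_only(self, tmp_path):
        path = tmp_path / "t.gff3"
        write_gff([], path)
        assert path.read_text() == "##gff-version 3\n"

    def test_single_row_three_linked_features(self, tmp_path):
        path = tmp_path / "t.gff3"
        write_gff([make_row()], path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert [l.split("\t")[2] for l in lines] == ["CPS", "APS", "motif"]
        assert "ID=cps00001" in lines[0]
        assert "Parent=cps00001" in lines[1] and "Parent=cps00001" in lines[2]

    def test_convention_bed_start_is_gff_start_minus_one(self, tmp_path):
        row = make_row()
        gff_path, bed_path = tmp_path / "t.gff3", tmp_path / "t.bed"
        write_gff([row], gff_path)
        write_bed(bed_path, [(row.seqid, row.aps_start, row.aps_end, "aps")], [], [])
        gff_aps = next(
            l for l in gff_path.read_text().splitlines() if "\tAPS\t" in l
        ).split("\t")
        bed_aps = parse_bed(bed_path)["aps"][0]
        assert bed_aps[1] == int(gff_aps[3]) - 1
        assert bed_aps[2] == int(gff_aps[4])

    def test_round_trip_through_gff3_reader(self, tmp_path, planted_scan):
        genome, scans = planted_scan
        rows = [r for _, region, result in scans for r in rows_for_gene(region, result)]
        path = tmp_path / "t.gff3"
        write_gff(rows, path)
        for feature_type, starts, ends in (
            ("CPS", "cps_start", "cps_end"),
            ("APS", "aps_start", "aps_end"),
            ("motif", "motif_start", "motif_end"),
        ):
            recovered = read_genes(path, feature_type=feature_type)
            got = {(g.start, g.end) for g in recovered}
            expected = {(getattr(r, starts), getattr(r, ends)) for r in rows}
            assert got == expected
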