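# aformscan

Most transcription factors recognise a base sequence (direct read-out), but
some recognise the *shape* the DNA adopts instead (indirect read-out).  One
documented case in *Xenopus* development couples an unusual A-form DNA
segment to a CCAAT box: the CBTF complex (via its ilf3 subunit) requires
both.  `aformscan` scans genomes for candidate promoters of this kind.

## What it computes

The scan is driven by the **A-DNA propensity energy (APE)**, a per-base
score in kcal/mol derived from a trinucleotide energy table T.  For
position *i* with bases *b*<sub>*i*−1</sub> *b*<sub>*i*</sub>
*b*<sub>*i*+1</sub>,

> APE(*i*) = T(*b*<sub>*i*−1</sub>*b*<sub>*i*</sub>*b*<sub>*i*+1</sub>) +
> T(revcomp(*b*<sub>*i*−1</sub>*b*<sub>*i*</sub>*b*<sub>*i*+1</sub>))

i.e. the sum over the forward- and reverse-strand triplets, which makes the
profile strand-symmetric.  Negative APE favours the A-form helix.  Fourteen
of the 64 triplets carry no energy value; positions depending on them (or
on sequence ends or ambiguity codes) are *undetermined* and never
contribute.

From the profile the scanner reports, within a window of `genegap` bp
(default 500) strictly upstream of each gene's transcription start site:

* **APS** (A-form promoter sequence): a maximal run of ≥ `apelen`
  (default 10) consecutive negative APE values, plus the two flanking bases
  the triplet calculation needs;
* **motif** occurrences: exact matches of each configured motif (default
  `CCAAT`) or its reverse complement;
* **CPS** (combined promoter sequence): an APS followed within ≤ `motifgap`
  bases (default 20) by a motif; the CPS spans APS start to motif end.

A Monte-Carlo null model draws i.i.d. windows at specified base frequencies
(defaults: the *X. tropicalis* genome composition), scans them identically,
and scales the fraction of APS/CPS-positive windows to the genome's gene
count, yielding the enrichment of observed elements over base composition
alone.

**Note on the packaged energy table** — the published per-triplet energies
are not redistributable here; the shipped `ape_table.synthetic.tsv` is a
clearly-labelled synthetic stand-in that reproduces the qualitative scale
(G/C tracts A-philic, A/T-rich triplets B-philic, 14 undetermined
triplets).  The engine is agnostic to the numbers: pass your own table with
`--ape-table` / `load_ape_table()` for quantitative work.

## Worked example

Generate a small synthetic genome with one planted APS+CCAAT element
upstream of each of three genes, then scan it:

```sh
aformscan synth --n-genes 3 --seed 11 --outdir demo --quiet
aformscan scan --genome demo/genome.fa --gff3 demo/genes.gff3 \
    --motif CCAAT --out-prefix demo/scan --quiet
cat demo/scan.tsv
```

```text
gene_id	gene_name	seqid	strand	tss	aps_start	aps_end	aps_run_length	motif_start	motif_end	motif_text	motif_orientation	gap	cps_start	cps_end
g001	synthg001	chrS	+	501	437	450	12	456	460	CCAAT	forward	5	437	460
g002	synthg002	chrS	-	1910	1961	1974	12	1951	1955	CCAAT	forward	5	1951	1974
g003	synthg003	chrS	+	2921	2857	2870	12	2876	2880	CCAAT	forward	5	2857	2880
```

Each row is one CPS: gene `g001` (plus strand, TSS at 501) carries a
14-bp flanked APS at chrS:437–450 (12 negative APE values), then a 5-bp
gap, then a forward CCAAT at 456–460; the whole CPS covers 437–460.  For
the minus-strand gene `g002` the upstream window lies to the *right* of the
gene and coordinates are reflected accordingly.  `--bed`, `--wig` and
`--gff` add genome-browser tracks (APS/motif locations, APE sign
segmentation, and the APE score profile); `aps` and `motifs` subcommands
run the structural or motif stage alone.

Null-model comparison (20,000 windows here; the observed count is whatever
your genome scan produced):

```sh
aformscan null --n 20000 --seed 11 --observed-cps 86 --quiet
```

reports, among other fields, `windows_with_aps: 233`,
`windows_with_cps: 31`, `expected_cps_genes: 28.6` and
`enrichment_cps: 3.01` — i.e. under the packaged synthetic table, 86
observed CPS-positive genes would be ~3× the compositional expectation.

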