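# Methods

## Scoring model

The per-base A-DNA propensity energy is a trinucleotide model: the score at
position *i* of a sequence depends only on bases *i*−1, *i*, *i*+1.  The
table stores *single-strand* energies for up to 64 triplets; the reported
per-base value is the sum of the forward-strand triplet energy and the
reverse-strand triplet energy (the reverse complement read 5′→3′).  Storing
single-strand values and computing the duplex sum keeps the data file at 64
rows and makes strand symmetry — profile(revcomp(s)) = reverse(profile(s))
— a structural property rather than a convention to maintain.

Undetermined values propagate strictly: a position is scored only if both
strand triplets are present in the table and all three bases are A/C/G/T.
The first and last positions of any sequence are always undetermined (no
flank).  Undetermined positions carry NaN and a `determined=False` mask
bit; they never contribute zero, and they terminate APS runs, matching the
view that an unknown energy is missing evidence, not neutral evidence.

## Element definitions

* **APS**: a maximal run of ≥ `apelen` consecutive positions that are
  determined and strictly negative.  An exact 0.0 breaks a run ("negative"
  is read strictly).  Only maximal runs are reported: a 15-long run at
  `apelen` 10 is one APS, not six nested ones — this is what makes APS
  counts well-defined.  The reported span adds the two flanking bases, so
  the default `apelen` 10 corresponds to a 12-bp element.
* **Motifs**: exact string matches of each configured motif and its reverse
  complement, case-insensitive, overlaps allowed.  A palindromic motif is
  reported once per position (forward).  Two configured motifs sharing an
  occurrence yield one hit each — deduplication across source motifs would
  discard provenance.
* **CPS**: every (APS, motif) pair where the motif starts strictly after
  the APS span (no overlap; overlap semantics are undefined for a coupled
  element) and the gap — bases strictly between span end and motif start —
  is ≤ `motifgap`.  One APS may pair with several motifs and vice versa.

Defaults are `motif=CCAAT`, `apelen=10`, `motifgap=20`, `genegap=500`:
CCAAT is the motif of the motivating CBTF/ilf3 system, 12 bp (10 + flanks)
is around the shortest element that reliably shows A-form character in
solution, 20 bp reflects the footprint of the CBTF complex, and 500 bp is
a conventional proximal-promoter window.

## Upstream windows and coordinates

The TSS is approximated by the 5′ end of the `gene` feature (the feature
type and attribute keys are configurable; transcript isoforms are not
consulted).  The scanned window is `[TSS−genegap, TSS−1]` — the TSS base
itself is excluded — clipped at contig edges, and read in gene sense:
minus-strand windows are reverse-complemented before scanning.  Because the
APE sum is strand-symmetric and motifs are searched with their reverse
complements, the CPS *set* is independent of which strand is scanned; only
the orientation labels are affected, and they are defined relative to the
gene sense (a "forward" CCAAT is on the coding strand of the downstream
gene).  Oriented hits map back to the reference through an affine
anchor+direction map; round-tripping is exact and tested.  Overlapping
upstream windows of neighbouring genes are scanned independently.

## The packaged energy table

The numeric per-triplet energies behind the published scale are not
redistributable in this package, so the shipped default
(`data/ape_table.synthetic.tsv`) is a synthetic stand-in, fixed once from
the qualitative structure of the scale: G/C blocks strongly A-philic
(GGG/CCC, GGC/GCC, CGG/CCG negative; alternating GCG/CGC not), single
A-in-G-block and T-heading-a-C-block variants weakly A-philic, ATGC-repeat
triplets weakly A-philic, A/T-rich triplets B-philic, and 14 triplets
undetermined (chosen among mixed-composition triplets, closed under
reverse complement).  Magnitudes are order 0.1–1 kcal/mol per strand.
Quantitative conclusions about real genomes require the true energies; the
entire algorithm layer is value-agnostic and all correctness tests run on
synthetic tables (`make_test_ape_table`), so swapping the table changes no
code path.

## Monte-Carlo null

The null draws windows i.i.d. base-by-base at fixed frequencies — the
default quadruple is the *X. tropicalis* genome composition — and counts
windows containing ≥ 1 APS and ≥ 1 CPS.  Window counts (not total element
counts) are scaled to the gene count so the expectation is directly
comparable to "genes with an element within `genegap` of the TSS", and the
CPS null uses the full motif set jointly, matching how genome-wide CPS
tallies are made.  Dinucleotide-preserving shuffles are deliberately out of
scope: the null models base composition only.

The implementation vectorises the scan over batches (triplet-index lookup,
flattened run detection, difference-array gap windows), but draws random
bases from the seeded generator in exactly the order a one-window-at-a-time
loop would, so for any seed the batched counts equal scanning the same
sequences individually through `scan_region` — an equality the tests assert
directly.  Results record the seed and are reproducible bit-for-bit;
batch size does not affect the stream.  The acceptance script runs 10⁶
windows of 500 bp (about 30 s on one CPU); the test suite uses 10⁵ with
proportionally wider binomial tolerance.

## Synthetic genomes

The fixture generator plants G-runs (with A/T guard bases pinning the run
boundaries) and motif copies at controlled gaps inside upstream windows, on
both strands, and emits FASTA + GFF3 + an exact truth table.  Background
sequence in a planted window is resampled until it contains no unplanned
G/C run of APS length and no guard-motif occurrence starting inside the
coupling window, so the truth table is exact by construction; the scanner
is never consulted during generation, which keeps recovery tests
independent.  Under the `gc_negative` test table (negative iff the central
base is G/C) APS runs coincide exactly with G/C tracts, making truth
coordinates provable by string inspection.  What the generator does *not*
emulate: isochore-scale composition variation, repeats, real promoter
architecture, or transcript-level TSS heterogeneity — passing recovery
tests demonstrates coordinate and detection correctness, not biological
realism.

## Output conventions

TSV and GFF3 are 1-based inclusive; BED is 0-based half-open (BED start =
GFF3 start − 1); WIG is fixedStep 1-based with step=span=1.  WIG blocks
break at undetermined positions instead of writing sentinel values, which
would corrupt browser autoscaling.  The BED sign track labels each position
`neg`/`pos`/`undet`, with exactly 0.0 labelled `pos` — only `neg` segments
matter to APS semantics.  All writers sort their input and are
byte-deterministic.  bigWig/bigBed conversion is left to the standard UCSC
converters.

## Degenerate inputs and edge cases

Empty sequences, windows shorter than three bases, genes whose TSS touches
a contig edge (empty window), headers-only GFF3 files, and empty FASTA
files all yield empty results rather than errors.  Genes lacking an ID
attribute or a +/− strand are skipped with a warning.  Malformed table or
GFF3 lines raise errors naming the line.  `apelen` < 1, negative
`motifgap`, and frequency vectors that are negative or do not sum to 1
within 10⁻⁶ are rejected.
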