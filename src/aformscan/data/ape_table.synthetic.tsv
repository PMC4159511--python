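# Single-strand trinucleotide A-DNA propensity energies (kcal/mol).
# SYNTHETIC stand-in table: reconstructed qualitative scale, not the
# published energies (which this distribution cannot reproduce).
# Negative = A-philic; 'X' = undetermined (14 triplets).
# Columns: TRIPLET<TAB>VALUE
AAA	0.48
AAC	0.30
AAG	0.28
AAT	0.42
ACA	X
ACC	0.15
ACG	0.10
ACT	X
AGA	X
AGC	0.17
AGG	-0.20
AGT	X
ATA	0.50
ATC	X
ATG	-0.28
ATT	0.42
CAA	0.33
CAC	0.18
CAG	0.22
CAT	-0.28
CCA	0.12
CCC	-0.65
CCG	-0.45
CCT	-0.20
CGA	0.15
CGC	0.20
CGG	-0.45
CGT	0.10
CTA	X
CTC	-0.18
CTG	0.22
CTT	0.28
GAA	0.35
GAC	0.20
GAG	-0.18
GAT	X
GCA	-0.25
GCC	-0.50
GCG	0.20
GCT	0.17
GGA	-0.22
GGC	-0.50
GGG	-0.65
GGT	0.15
GTA	X
GTC	0.20
GTG	0.18
GTT	0.30
TAA	0.45
TAC	X
TAG	X
TAT	0.50
TCA	X
TCC	-0.22
TCG	0.15
TCT	X
TGA	X
TGC	-0.25
TGG	0.12
TGT	X
TTA	0.45
TTC	0.35
TTG	0.33
TTT	0.48
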