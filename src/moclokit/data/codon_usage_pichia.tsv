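codon	amino_acid	per_thousand
TTT	F	24.1
TTC	F	19.6
TTA	L	15.5
TTG	L	31.8
CTT	L	16.7
CTC	L	7.8
CTA	L	11.4
CTG	L	15.2
ATT	I	31.2
ATC	I	18.4
ATA	I	12.0
ATG	M	18.7
GTT	V	27.0
GTC	V	14.8
GTA	V	9.8
GTG	V	10.9
TCT	S	23.6
TCC	S	15.1
TCA	S	18.0
TCG	S	7.4
AGT	S	12.5
AGC	S	7.9
CCT	P	15.8
CCC	P	6.7
CCA	P	17.0
CCG	P	4.4
ACT	T	22.6
ACC	T	13.7
ACA	T	15.2
ACG	T	5.9
GCT	A	29.2
GCC	A	16.9
GCA	A	16.1
GCG	A	3.6
TAT	Y	15.5
TAC	Y	18.7
TAA	*	1.0
TAG	*	0.8
TGA	*	0.4
CAT	H	10.9
CAC	H	8.9
CAA	Q	25.8
CAG	Q	15.0
AAT	N	24.5
AAC	N	25.8
AAA	K	29.9
AAG	K	34.1
GAT	D	35.7
GAC	D	22.3
GAA	E	38.2
GAG	E	28.7
TGT	C	7.4
TGC	C	4.0
TGG	W	10.3
CGT	R	6.5
CGC	R	2.2
CGA	R	4.0
CGG	R	1.7
AGA	R	21.2
AGG	R	7.4
GGT	G	26.6
GGC	G	9.6
GGA	G	19.0
GGG	G	5.7
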