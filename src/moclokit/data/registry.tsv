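name	role	gene	orf_id	regulation	strength_G	strength_X	strength_D	strength_M	repressed_strength	induced_strength
P_GAP	promoter	TDH3	PP7435_Chr2-0858	constitutive	100	100	100	100
P_GPM1	promoter	GPM1	PP7435_Chr3-0360	constitutive	25	13	26	11
P_RPP1B	promoter	RPP1B	PP7435_Chr4-0276	constitutive	22	14	23	13
P_PDC1	promoter	PDC1	PP7435_Chr3-1042	constitutive	19	17	23	16
P_POR1	promoter	POR1	PP7435_Chr2-0411	constitutive	46	28	19	51
P_MDH3	promoter	MDH3	PP7435_Chr4-0136	constitutive	76	83	17	110
P_ADH2	promoter	ADH2	PP7435_Chr2-0821	constitutive	33	47	16	54
P_FBA1-1	promoter	FBA1-1	PP7435_Chr1-0374	constitutive	20	11	14	12
P_SHB17	promoter	SHB17	PP7435_Chr2-0185	methanol_induced	0	0	0	53	0	53
P_TEF2	promoter	TEF2	PP7435_Chr1-1535	constitutive			53
P_RPL2A	promoter	RPL2A	PP7435_Chr4-0909	constitutive			10
P_LAT1	promoter	LAT1	PP7435_Chr1-0349	constitutive			6
P_PFK300	promoter	PFK300	PP7435_Chr4-0686	constitutive			2
P_GUT1	promoter	GUT1	PP7435_Chr4-0173	glycerol_induced	44		1		0	44
P_THI11	promoter	THI11	PP7435_Chr4-0952	thiamine_repressed			36		0	36
P_DAS2	promoter	DAS2	PP7435_Chr3-0350	methanol_induced			0	160	0	160
P_AOX1	promoter	AOX1	PP7435_Chr4-0130	methanol_induced			0	105	0	105
P_DAS1	promoter	DAS1	PP7435_Chr3-0352	methanol_induced			0	99	0	99
P_FDH1	promoter	FDH1	PP7435_Chr3-0238	methanol_induced			0	83	0	83
P_ALD4	promoter	ALD4	PP7435_Chr2-0787	methanol_induced			0	18	0	18
ScCYC1tt	terminator	CYC1	Sc:YJR048W	not_applicable	100	100	100
TDH3tt	terminator	TDH3	PP7435_Chr2-0858	not_applicable	139	128	126
RPS2tt	terminator	RPS2	PP7435_Chr1-1396	not_applicable	136	129	128
RPP1Btt	terminator	RPP1B	PP7435_Chr4-0276	not_applicable	120	117	113
RPS17Btt	terminator	RPS17B	PP7435_Chr2-0491	not_applicable	124	122	118
chr4_0883tt	terminator	chr4_0883	PP7435_Chr4-0069	not_applicable	88	99	84
IDP1tt	terminator	IDP1	PP7435_Chr1-0546	not_applicable	126	123	118
RPS25Att	terminator	RPS25A	PP7435_Chr2-0346	not_applicable	140	126	123
RPS3tt	terminator	RPS3	PP7435_Chr1-0118	not_applicable	137	125	123
RPL2Att	terminator	RPL2A	PP7435_Chr4-0909	not_applicable	102	102	93
RGI2	integration_locus	RGI2		not_applicable
ENO1	integration_locus	ENO1		not_applicable
NTS	integration_locus	NTS		not_applicable
AOX1tt	integration_locus	AOX1		not_applicable
CEN_ARS	episomal_locus	ScCEN/ARS		not_applicable
hphMX	resistance_marker	hph		not_applicable
natMX	resistance_marker	nat		not_applicable
kanMX	resistance_marker	kan		not_applicable
ZeoR_loxP	resistance_marker	ble		not_applicable
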