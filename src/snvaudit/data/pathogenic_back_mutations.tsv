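chrom	pos	ref	alt	gene	hgvs	clinvar	hgmd_class	ancestral
1	1000000	A	G	ABCA4	NM_000350.2:c.1268A>G	Benign;Likely benign	DM	G
2	1001000	G	A	ABCC6	NM_001171.5:c.3961G>A	Pathogenic	.	A
3	1002000	T	C	ABCC6	NM_001171.5:c.1233T>C	Likely benign	DM	C
4	1003000	T	C	ANK1	NM_000037.3:c.-108T>C	Pathogenic	DM?	C
5	1004000	C	G	ARSA	NM_000487.5:c.1178C>G	Benign;Pathogenic	DP	G
6	1005000	T	C	ASPM	NM_018136.4:c.7787T>C	Benign	DM	C
7	1006000	G	A	BCL11A	NM_018014.3:c.386-24278G>A	Likely pathogenic	.	A
8	1007000	C	T	CBS	NM_000071.2:c.992C>T	Pathogenic	.	T
9	1008000	G	A	CLCN7	NM_001287.5:c.1252G>A	Benign	DM	A
10	1009000	G	A	COL4A4	NM_000092.4:c.3979G>A	Likely pathogenic	.	A
11	1010000	C	T	CRYAB	NM_001885.2:c.166C>T	Pathogenic	.	T
12	1011000	T	C	DHCR7	NM_001360.2:c.438T>C	Benign	DM	C
13	1012000	T	C	DPYD	NM_000110.3:c.85T>C	Pathogenic	DFP	C
14	1013000	G	A	DRAM2	NM_178454.4:c.131G>A	Pathogenic	.	A
15	1014000	T	C	EYA1	NM_000503.5:c.1755T>C	Benign	DM	C
16	1015000	G	A	FBN1	NM_000138.4:c.2180G>A	Pathogenic	.	A
17	1016000	T	C	FGFR1	NM_023110.2:c.899T>C	Pathogenic	.	C
18	1017000	A	G	GJB2	NM_004004.5:c.487A>G	Likely benign;Pathogenic	.	G
19	1018000	C	T	HEPACAM	NM_152722.4:c.274C>T	Pathogenic	.	T
20	1019000	T	C	KEL	NM_000420.2:c.1790T>C	Pathogenic	FP	C
21	1020000	T	C	KRT1	NM_000526.4:c.369T>C	.	DM	C
22	1021000	G	A	MAK	NM_001242957.1:c.37G>A	Pathogenic	.	A
1	1022000	C	G	MYH7	NM_000257.3:c.5507C>G	Pathogenic	.	G
2	1023000	C	T	NPHS1	NM_004646.3:c.1219C>T	Likely pathogenic	.	T
3	1024000	G	C	OTOF	NM_194248.2:c.2736G>C	Benign	DM	C
4	1025000	C	G	RAF1	NM_002880.3:c.781C>G	Pathogenic	.	G
5	1026000	G	A	RARS2	NM_020320.3:c.953G>A	Likely pathogenic	.	A
6	1027000	A	G	SCN5A	NM_198056.2:c.1673A>G	Benign;Pathogenic	DFP	G
7	1028000	G	A	SLC17A5	NM_012434.4:c.983G>A	Likely pathogenic	.	A
8	1029000	C	G	SLC45A2	NM_016180.4:c.1122C>G	Association;Protective	DM	G
9	1030000	A	G	SLC45A2	NM_016180.4:c.987A>G	Benign	DM	G
10	1031000	C	T	SPG11	NM_025137.3:c.7023C>T	Benign	DM	T
11	1032000	A	G	STAT1	NM_007315.3:c.494A>G	Pathogenic	.	G
12	1033000	T	G	TAS2R16	NM_016945.2:c.516T>G	Pathogenic;risk factor	DFP	G
13	1034000	A	G	XDH	NM_000379.3:c.3276+12A>G	Likely pathogenic	.	G
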