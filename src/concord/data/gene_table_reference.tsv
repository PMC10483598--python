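gene	tissue_n	ctdna_n	mutual_gene_n	mutual_mutation_n
TP53	196	158	110	69
KRAS	81	56	36	11
EGFR	45	43	16	6
PIK3CA	44	42	19	6
APC	40	20	16	14
MYC	28	25	8	3
PTEN	26	12	10	9
ERBB2	23	15	8	6
CDKN2A	22	8	6	5
ARID1A	20	7	3	3
SMAD4	18	9	6	4
BRAF	17	31	8	3
IDH1	17	2	1	0
FBXW7	11	3	2	2
BRCA2	10	3	1	1
GNAS	10	9	3	2
NF1	10	9	1	1
CTNNB1	9	6	4	3
ATM	8	7	1	1
CCNE1	8	16	3	1
ESR1	8	5	4	2
FGFR1	8	12	4	2
MET	8	23	4	2
CDK4	7	3	1	1
KIT	6	6	1	2
FGFR2	5	2	2	1
NRAS	5	4	1	1
AKT1	4	2	1	1
FGFR3	4	1	1	1
MAP2K1	4	2	2	2
VHL	4	3	2	1
HRAS	2	2	1	1
GNA11	1	1	1	1
GNAQ	1	1	1	1
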