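symbol	sera_mild	hits_mild	sera_control	hits_control	annotations
RIF1	2	43	5	105	6
ZNF142	0	0	4	67
BAZ1A	0	0	4	39
LAMA3	1	2	4	46	1,2
NAV2	2	34	4	70	1,3,4
OBSCN	2	17	4	32
MT-CO1	2	9	4	22	1,6
LRP1B	2	6	4	17	1,6
PITRM1	0	0	3	94	1,4,7
PCSK5	0	0	3	56	1,2
ITPR1	0	0	3	52	3,4,7
OAS1	0	0	3	51	1
UNC8	0	0	3	51	4
KLHL29	0	0	3	50	1,2,7
DIAPH3	0	0	3	49	3
POTEB3	0	0	3	43	1
STAB2	0	0	3	39	2
CASP8AP2	0	0	3	32
GATAD2A	0	0	3	32	3
GRN	0	0	3	32	1,2,3,4,5,6,7
TUBGCP6	0	0	3	31
THSD7B	0	0	3	30
ADAMTS13	0	0	3	29	1,2,6
AMBP	0	0	3	28	7
PDE9A	0	0	3	27	1,5
SH3PXD2A	0	0	3	27	1,5
STK36	0	0	3	27	3,4
STXBP5L	0	0	3	26	1
PLXNB2	0	0	3	25	2,3,6
ZNF592	0	0	3	23	1
CLDN7	0	0	3	22	2,6
CRB2	0	0	3	22	2,3,6,7
YEATS2	0	0	3	22
CRYBG2	0	0	3	21	1
CSMD1	0	0	3	21	1,2,3
DNMBP	0	0	3	21	1
WNT8A	0	0	3	21	2,3,6
LILRA2	0	0	3	20	2
ADAMTS16	0	0	3	19
IGLL1	0	0	3	19
ITGB2	0	0	3	19	1
PARP4	0	0	3	19	1
CTCF	0	0	3	16	1,2,3,7
IGSF1	0	0	3	16
BOC	0	0	3	14	3
LRRC4	0	0	3	14
SNTB2	0	0	3	11
MC1R	0	0	3	10	1,2,4,5,6
RAB3GAP2	0	0	3	9	1
POTEB	0	0	3	3	2
CYP4F11	1	8	3	143
KMT2A	1	9	3	124	3
ADAMTS7	1	18	3	50	2,6
KAT5	1	5	3	48	3
PTPRQ	1	5	3	40	1
TSHZ2	1	9	3	36	1
KIF13B	1	9	3	35	3,4
RGS12	1	11	3	33	4
REXO1	1	3	3	32
CASZ1	1	8	3	26	2,3
BCR	1	5	3	25	6
LRP6	1	11	3	24	1,2,3,4,5,6
DNAH12	1	6	3	22
ITGB1BP2	1	3	3	11	1
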