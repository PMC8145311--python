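symbol	sera_mild	hits_mild	sera_control	hits_control	annotations
SSPO	8	162	4	57	2,3,7
VWF	6	158	1	15	1,2,3,4,5,6
IGKC	5	130	1	3	1,2
F8	4	84	0	0	1,2,3
CR1	4	30	0	0	1,2,3,5,7
UPF2	4	30	0	0	2,3
LTBP2	4	66	1	5
ADGRV1	4	66	1	15	3
SVEP1	4	56	1	7
LRP4	4	42	1	5	2,3
ZNF469	4	37	1	5
FBN1	4	28	1	14	1,2,3,4,5
MT1B	4	17	1	3
MT-ND1	4	127	2	25	1
OTOGL	4	74	2	25
NOTCH1	4	39	2	22	1,2,3,4,5,6,7
LRP1	4	34	2	13	1,2,3,4,5,6,7
DLGAP5	3	115	0	0	7
BSG	3	72	0	0	1,2,7
NFXL1	3	59	0	0
KIAA119	3	55	0	0
TNRC6A	3	53	0	0	6
ATP1A1	3	52	0	0	1,2,4,6
SPINK5	3	51	0	0	2
PCDH8	3	46	0	0	4
ARHGEF2	3	45	0	0	2,3
CFAP221	3	45	0	0
EYA1	3	45	0	0	3,6
SARDH	3	44	0	0
RALGAPA2	3	41	0	0	2
STXBP2	3	40	0	0	2,3
PKD1P6	3	39	0	0
KMT2E	3	37	0	0	2,3
SRRM2	3	37	0	0	1
CNOT1	3	35	0	0
POU4F3	3	35	0	0	2,3
CYLD	3	33	0	0	2,3,4,6,7
CAPN3	3	32	0	0	4
ITGAX	3	32	0	0	1,2,6
SMCHD1	3	30	0	0
GIT1	3	29	0	0	1,2,4,5,6,7
ACACB	3	27	0	0	1,2,3
C5orf42	3	26	0	0	4
KHSRP	3	26	0	0	2
OR7G1	3	26	0	0
ASCC1	3	25	0	0	2
MFRP	3	25	0	0
SSC5D	3	25	0	0	2
HNRNPA3	3	23	0	0	1,3
RXFP3	3	23	0	0	1,6
AGAP2	3	22	0	0	1,7
NAAA	3	22	0	0	1,2
MEGF11	3	21	0	0
ATMIN	3	19	0	0	3,6
EGR1	3	18	0	0	1,2,3,4,5,6,7
GOLGA2P11	3	16	0	0
LOC4682	3	16	0	0
TENM1	3	15	0	0
PCDHA4	3	13	0	0	1
TNFAIP3	3	13	0	0	2,3
ZC3H4	3	12	0	0
NOXP20	3	11	0	0
ARIH1	3	9	0	0
OIT3	3	8	0	0	4
IGLC3	3	259	1	2
CHFR	3	169	1	22	2,3,6
POGZ	3	126	1	26	3
AGAP6	3	119	1	3	3
LTBP1	3	118	1	25	1
HSPG2	3	73	1	3	1,3,5,6
PRUNE2	3	59	1	7
FRMPD1	3	32	1	9
RYR3	3	32	1	15	1,2,3,4,6
MIDN	3	27	1	6	2,3,5,7
CELSR2	3	25	1	4	3
SEC24C	3	25	1	5	1,7
NBPF10	3	24	1	3	1,7
FREM2	3	24	1	7
KMT2C	3	24	1	11	3
MT-ND6	3	22	1	8	1
PDZD2	3	22	1	9
ADAMTS6	3	19	1	3
MALRD1	3	17	1	8	3
PCDHB7	3	16	1	7
SPEN	3	15	1	5	3,7
MYCBP2	3	15	1	6	3
HLA-DQA1	3	14	1	5
TRIP11	3	13	1	5
POLA1	3	9	1	3
CDCA2	3	8	1	3	3
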