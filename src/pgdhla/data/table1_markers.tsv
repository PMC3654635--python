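name	chromosome	region	order_index	primer_fwd	primer_rev	dye	size_min	size_max
D6S1571	6	UPSTREAM_HLA_A	1	GGACCTACGCATCTGGTG	TGGCTCTAATGGTTACTTTTTACA	PET	160	180
D6S1260	6	UPSTREAM_HLA_A	2	ACTGCTCCTGGGCATGGTTG	GTACATGCCTTTGTTAACATC	NED	130	160
D6S1624	6	UPSTREAM_HLA_A	3	GGAAGTCTTCAGTGGAGAGAGT	ACTCCAGGTGTTTGTGGTTT	6FAM	200	220
MOG-CA	6	UPSTREAM_HLA_A	4	TCACCTCGAGTGAGTCTCTTT	ACCATGGGTAACTGAAGCAT	VIC	205	235
MOG-TAAA	6	UPSTREAM_HLA_A	5	GAAATGTGAGAATAAAGGAGA	GATAAAGGGGAACTACTACA	6FAM	125	150
D6S265	6	HLA_A__HLA_B	6	ACGTTCGTACCCATTAACCT	CGAGGTAAACAGCAGAAAGA	6FAM	110	125
HLAC-CA	6	HLA_A__HLA_B	7	TCCCTAGTAGCTGGGATTACA	CGGCAAGAGACTCTGATGA	VIC	155	175
MIB	6	HLA_B__HLA_DRA	8	CCACAGTCTCTATCAGTCCAGA	TCAGCCTGCTAGCTTATCCT	6FAM	155	185
D6S273	6	HLA_B__HLA_DRA	9	GGCCAAAGTTAAAACCAAAC	GCAACTTTTCTGTCAATCCA	6FAM	135	145
D6S1618	6	HLA_B__HLA_DRA	10	GGCCTGAGCAGTGCAT	TGATTCCTAATCTGCGGG	NED	130	170
DRA-CA	6	HLA_DRA__HLA_DQB1	11	GATACTTTCCTAATTCTCCTCCTTC	ATGGAATCTCATCAAGGTCAG	VIC	120	140
D6S2443	6	HLA_DRA__HLA_DQB1	12	CCATACCAAAGTAAAACCCAG	GAGGATGAAGGGAAATTAGAG	6FAM	150	200
DQCAR	6	HLA_DRA__HLA_DQB1	13	CTTGGCCAATCAGAATCTTT	CTGCATTTCTCTTCCTTATCAC	PET	150	175
TAP1-CA	6	DOWNSTREAM_HLA_DQB1	14	GGACAATATTTTGCTCCTGA	TCATACATCTGCTTTGATCTCC	PET	195	215
RING3-CA	6	DOWNSTREAM_HLA_DQB1	15	GGGCCGCAGTTTAAGTAAC	TGTTAGGTCAGAACCACAGAA	6FAM	125	135
D6S1560	6	DOWNSTREAM_HLA_DQB1	16	CTCCAGTCCCCACTGC	CCCAAGGCCACATAGC	6FAM	225	250
D6S1583	6	DOWNSTREAM_HLA_DQB1	17	GCCCCTAACCTGCTTCTACTGA	GCAGATGGCCCCACTGAC	VIC	150	200
D6S1611	6	DOWNSTREAM_HLA_DQB1	18	GAGCAAGACTCCATCTCAAA	ACCTAAGTTCTCTGAAGGGC	PET	225	250
D6S1610	6	DOWNSTREAM_HLA_DQB1	19	CCTGGTGAGATAGATGCTTG	ATTTCCAGCAGAGCCTTG	PET	100	140
D6S1552	6	DOWNSTREAM_HLA_DQB1	20	AGCCTGAACGACAGAACAAG	CTGCTTAACTTAGATCTTTGGTAT	VIC	160	200
D11S1338	11	BG_5PRIME	1	GACGGTTTAACTGTATATCTAAGAC	TAATGCTACTTATTTGGAGTGTG	6FAM	250	280
D11S4891	11	BG_5PRIME	2	GGAAATGGACCTCTGTCTC	CTTTTATTCCAGCCCCAC	6FAM	75	100
D11S1760	11	BG_5PRIME	3	GATCTCAAGTGTTTCCCCAC	AAACGATGTCTGTCCACTCA	PET	75	100
D11S1871	11	BG_3PRIME	4	AAGAAGTTGCCCTGATGTCT	TAAAAGGAGCTGAATGCACA	PET	160	200
D11S2351	11	BG_3PRIME	5	GGGCACCTGTAATCCCA	AGGAGTCACTGGATCTACTC	6FAM	150	180
D11S4181	11	BG_3PRIME	6	AAGCTTCCTTCACATTCTTACAG	GAACTGAGACCAAGAACATTATTCC	6FAM	200	225
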