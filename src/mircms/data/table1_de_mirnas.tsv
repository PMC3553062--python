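uniqid	sequence	norm_MF	norm_CMS	p_AC	p_Fisher	p_Chi2x2	direction
ath-MIR156a-p3	TGCTCACTGCTCTTTCTGTCAGA	50	0	0	0	0	down
ath-MIR156e-p3	GCTTACTCTCTCTCTGTCACC	91	9	0	0	0	down
ath-miR156h_L+1	TTGACAGAAGAAAGAGAGCAC	14	47	0.000005	0.000027	0.000024	up
ath-miR158a	TCCCAAATGTAGACAAAGCA	31	1	0	0	0	down
ath-miR159a	TTTGGATTGAAGGGAGCTCTA	3375	5739	0	0	0	up
ath-MIR159a-p5	AGCTGCTAAGCTATGGATCCC	54	12	0	0	0	down
ath-miR159c_R-2	TTTGGATTGAAGGGAGCTC	77	17	0	0	0	down
ath-miR164a	TGGAGAAGCAGGGCACGTGCA	253	472	0	0	0	up
ath-miR164b	TGGAGAAGCAGGGCACGTGCA	253	472	0	0	0	up
ath-miR164c	TGGAGAAGCAGGGCACGTGCG	102	51	0.000006	0.000046	0.000037	down
ath-MIR164c-p3	CACGTGTTCTACTACTCCAAC	1	17	0.000034	0.000145	0.000162	up
ath-miR165a	TCGGACCAGGCTTCATCCCCC	3116	4420	0	0	0	up
ath-miR165b	TCGGACCAGGCTTCATCCCCC	3116	4420	0	0	0	up
ath-miR166a	TCGGACCAGGCTTCATTCCCC	2589	3591	0	0	0	up
ath-miR166b	TCGGACCAGGCTTCATTCCCC	2589	3591	0	0	0	up
ath-miR166c	TCGGACCAGGCTTCATTCCCC	2589	3591	0	0	0	up
ath-miR166d	TCGGACCAGGCTTCATTCCCC	2589	3591	0	0	0	up
ath-miR166e	TCGGACCAGGCTTCATTCCCC	2589	3591	0	0	0	up
ath-miR166f	TCGGACCAGGCTTCATTCCCC	2589	3591	0	0	0	up
ath-miR166g	TCGGACCAGGCTTCATTCCCC	2589	3591	0	0	0	up
ath-miR167a	TGAAGCTGCCAGCATGATCTA	6244	864	0	0	0	down
ath-MIR167a-p3	GATCATGTTCGCAGTTTCACC	568	83	0	0	0	down
ath-miR167b	TGAAGCTGCCAGCATGATCTA	6244	864	0	0	0	down
ath-miR167d_R-2	TGAAGCTGCCAGCATGATCT	359	42	0	0	0	down
ath-MIR169e-p3	GCAAGTTGACTTTGGCTCTGT	141	39	0	0	0	down
ath-miR319a	TTGGACTGAAGGGAGCTCCCT	45330	82597	0	0	0	up
ath-miR319b	TTGGACTGAAGGGAGCTCCCT	45330	82597	0	0	0	up
ath-MIR319b-p5	GAGCTTTCTTCGGTCCACTC	0	20	0	0.000002	0.000008	up
ath-miR390a	AAGCTCAGGAGGGATAGCGCC	289	527	0	0	0	up
ath-MIR390a-p3_1ss5AG	CGCTGTCCATCCTGAGTTTCA	52	102	0.000009	0.000069	0.000056	up
ath-miR390b	AAGCTCAGGAGGGATAGCGCC	289	527	0	0	0	up
ath-miR395a	CTGAAGTGTTTGGGGGAACTC	36	7	0.000002	0.000009	0.00001	down
ath-miR395d	CTGAAGTGTTTGGGGGAACTC	36	7	0.000002	0.000009	0.00001	down
ath-miR395c	CTGAAGTGTTTGGGGGAACTC	36	7	0.000002	0.000009	0.00001	down
ath-miR396b	TTCCACAGCTTTCTTGAACTT	260	171	0.000002	0.000021	0.000018	down
ath-miR408	ATGCACTGCCTCTTCCCTGGC	805	1272	0	0	0	up
ath-MIR408-p5	ACAGGGAACAAGCAGAGCATG	39	117	0	0	0	up
ath-miR845a	CGGCTCTGATACCAATTGATG	121	53	0	0	0	down
peu-MIR2916-p3	TCTCAACCATAAACGATGCCGACC	523	335	0	0	0	down
peu-MIR2916-p5	GTCTCAACCATAAACGATGCCGAC	316	228	0.000014	0.000185	0.000161	down
ahy-miR167-5p_1ss21TC	TGAAGCTGCCAGCATGATCTC	80	2	0	0	0	down
ahy-miR159_1ss7TC	TTTGGACTGAAGGGAGCTCTA	33	6	0.000003	0.000014	0.000015	down
rco-miR319d_2ss20TC21TA	TTGGACTGAAGGGAGCTCCCA	201	83	0	0	0	down
peu-MIR2911-p3_1ss6CT	GCGTGTCGGCCGGGGGACGGGCTG	19	0	0.000001	0.000004	0.000013	down
peu-MIR2911-p5_1ss3TA	GGAGGACTGCTCGAGCTGC	18	1	0.000018	0.000076	0.000096	down
smo-MIR1103-p3	GTGACCTCCCGGGAAGTCC	179	117	0.000034	0.000374	0.000313	down
PC-3p-77	GCGATTTGTCTGGTTAATTCCGTT	199	94	0	0	0	down
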