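Genes	Start	End	Strand	Size	Intergenic nucleotide	Anti-codon	Start codon	Stop codon
tRNA-Phe	1	69	H	69	0	GAA	.	.
12S rRNA	70	1022	H	953	0	.	.	.
tRNA-Val	1023	1094	H	72	0	TAC	.	.
16S rRNA	1095	2775	H	1681	0	.	.	.
tRNA-Leu(L2)	2776	2851	H	76	0	TAA	.	.
ND1	2852	3826	H	975	4	.	ATG	TAA
tRNA-Ile	3831	3902	H	72	-2	GAT	.	.
tRNA-Gln	3901	3971	L	71	1	TTG	.	.
tRNA-Met	3973	4041	H	69	0	CAT	.	.
ND2	4042	5086	H	1045	0	.	ATG	T--
tRNA-Trp	5087	5157	H	71	2	TCA	.	.
tRNA-Ala	5160	5228	L	69	1	TGC	.	.
tRNA-Asn	5230	5302	L	73	33	GTT	.	.
tRNA-Cys	5336	5402	L	67	-1	GCA	.	.
tRNA-Tyr	5402	5472	L	71	1	GTA	.	.
COI	5474	7021	H	1548	-1	.	GTG	TAA
tRNA-Ser(S2)	7021	7092	L	72	3	TGA	.	.
tRNA-Asp	7096	7167	H	72	14	GTC	.	.
COII	7182	7872	H	691	0	.	ATG	T--
tRNA-Lys	7873	7948	H	76	1	TTT	.	.
ATP8	7950	8114	H	165	-7	.	ATG	TAG
ATP6	8108	8790	H	683	0	.	ATG	TA-
COIII	8791	9575	H	785	0	.	ATG	TA-
tRNA-Gly	9576	9648	H	73	0	TCC	.	.
ND3	9649	9997	H	349	0	.	ATG	T--
tRNA-Arg	9998	10067	H	70	0	TCG	.	.
ND4L	10068	10364	H	297	-7	.	ATG	TAA
ND4	10358	11738	H	1381	0	.	ATG	T--
tRNA-His	11739	11807	H	69	0	GTG	.	.
tRNA-Ser(S1)	11808	11877	H	70	1	GCT	.	.
tRNA-Leu(L1)	11879	11951	H	73	3	TAG	.	.
ND5	11955	13778	H	1824	-4	.	ATG	TAA
ND6	13775	14296	L	522	0	.	ATG	TTA
tRNA-Glu	14297	14365	L	69	5	TTC	.	.
Cytb	14371	15511	H	1141	0	.	ATG	TT-
tRNA-Thr	15512	15583	H	72	-1	TGT	.	.
tRNA-Pro	15583	15653	L	71	0	TGG	.	.
CR	15654	16571	H	918	.	.	.	.
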