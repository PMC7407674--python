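# synthetic default table: quasi-chemical inversion of a 1000000-contact library sampled from a hydropathy+charge seed potential (scripts/make_default_table.py, seed 20260924); not derived from any structural database; contacts=1000000
res_i	res_j	u_sc
ALA	ALA	-0.012798
ALA	ARG	0.020969
ALA	ASN	0.001654
ALA	ASP	0.040170
ALA	CYS	-0.014407
ALA	GLN	0.007513
ALA	GLU	0.015049
ALA	GLY	-0.011520
ALA	HIS	0.001144
ALA	ILE	0.003949
ALA	LEU	-0.011107
ALA	LYS	0.013107
ALA	MET	-0.006675
ALA	PHE	-0.004883
ALA	PRO	-0.015358
ALA	SER	-0.025785
ALA	THR	0.007083
ALA	TRP	-0.001747
ALA	TYR	0.037494
ALA	VAL	-0.015422
ARG	ARG	0.397799
ARG	ASN	0.006729
ARG	ASP	-0.380087
ARG	CYS	0.002175
ARG	GLN	-0.013820
ARG	GLU	-0.349780
ARG	GLY	0.011623
ARG	HIS	0.050918
ARG	ILE	-0.008807
ARG	LEU	0.013513
ARG	LYS	0.409893
ARG	MET	-0.009888
ARG	PHE	0.022017
ARG	PRO	0.010221
ARG	SER	0.009637
ARG	THR	0.028467
ARG	TRP	0.022023
ARG	TYR	0.011941
ARG	VAL	0.025855
ASN	ASN	0.040578
ASN	ASP	-0.005520
ASN	CYS	-0.011071
ASN	GLN	-0.015945
ASN	GLU	0.012038
ASN	GLY	-0.007666
ASN	HIS	-0.019037
ASN	ILE	0.022383
ASN	LEU	0.002979
ASN	LYS	-0.000961
ASN	MET	-0.005169
ASN	PHE	-0.027211
ASN	PRO	-0.011233
ASN	SER	-0.001614
ASN	THR	0.019679
ASN	TRP	0.015407
ASN	TYR	-0.030054
ASN	VAL	0.014667
ASP	ASP	0.442230
ASP	CYS	0.024133
ASP	GLN	0.006369
ASP	GLU	0.389245
ASP	GLY	0.003283
ASP	HIS	0.019680
ASP	ILE	0.004226
ASP	LEU	-0.004322
ASP	LYS	-0.376423
ASP	MET	0.040040
ASP	PHE	-0.001167
ASP	PRO	-0.007034
ASP	SER	0.013294
ASP	THR	0.016293
ASP	TRP	0.012317
ASP	TYR	-0.005692
ASP	VAL	0.015134
CYS	CYS	-0.005939
CYS	GLN	-0.002234
CYS	GLU	-0.000163
CYS	GLY	0.015067
CYS	HIS	-0.017963
CYS	ILE	-0.001954
CYS	LEU	0.009805
CYS	LYS	-0.023072
CYS	MET	-0.010668
CYS	PHE	0.001732
CYS	PRO	-0.005117
CYS	SER	0.017976
CYS	THR	0.003997
CYS	TRP	0.021194
CYS	TYR	-0.000568
CYS	VAL	-0.002444
GLN	GLN	-0.036387
GLN	GLU	0.015967
GLN	GLY	0.045077
GLN	HIS	0.014294
GLN	ILE	0.014173
GLN	LEU	-0.010822
GLN	LYS	0.026386
GLN	MET	-0.002508
GLN	PHE	-0.012531
GLN	PRO	0.001973
GLN	SER	-0.002050
GLN	THR	-0.006237
GLN	TRP	-0.012956
GLN	TYR	0.002033
GLN	VAL	-0.012908
GLU	GLU	0.408201
GLU	GLY	-0.005269
GLU	HIS	0.017895
GLU	ILE	-0.014960
GLU	LEU	0.029615
GLU	LYS	-0.375880
GLU	MET	0.037664
GLU	PHE	-0.010109
GLU	PRO	0.033770
GLU	SER	0.035780
GLU	THR	0.014638
GLU	TRP	0.001689
GLU	TYR	-0.008543
GLU	VAL	-0.003561
GLY	GLY	0.019694
GLY	HIS	0.004721
GLY	ILE	-0.028988
GLY	LEU	-0.008569
GLY	LYS	0.013008
GLY	MET	0.017817
GLY	PHE	-0.011839
GLY	PRO	-0.031258
GLY	SER	0.004297
GLY	THR	-0.021706
GLY	TRP	0.018955
GLY	TYR	0.006523
GLY	VAL	-0.009900
HIS	HIS	-0.005669
HIS	ILE	-0.030071
HIS	LEU	0.001407
HIS	LYS	-0.003908
HIS	MET	0.009623
HIS	PHE	-0.000958
HIS	PRO	0.018219
HIS	SER	-0.008252
HIS	THR	-0.004215
HIS	TRP	-0.026635
HIS	TYR	0.010705
HIS	VAL	-0.005215
ILE	ILE	0.006166
ILE	LEU	-0.007440
ILE	LYS	0.016740
ILE	MET	-0.000077
ILE	PHE	0.006514
ILE	PRO	0.007615
ILE	SER	-0.002354
ILE	THR	0.009786
ILE	TRP	-0.004377
ILE	TYR	0.007105
ILE	VAL	0.001546
LEU	LEU	-0.008510
LEU	LYS	-0.005309
LEU	MET	0.008624
LEU	PHE	0.027257
LEU	PRO	0.005114
LEU	SER	-0.012166
LEU	THR	-0.027977
LEU	TRP	-0.006021
LEU	TYR	0.005458
LEU	VAL	0.001699
LYS	LYS	0.458068
LYS	MET	0.004251
LYS	PHE	0.045323
LYS	PRO	0.033630
LYS	SER	0.027760
LYS	THR	0.019974
LYS	TRP	0.022914
LYS	TYR	-0.002357
LYS	VAL	0.009794
MET	MET	-0.009887
MET	PHE	0.006153
MET	PRO	-0.002676
MET	SER	-0.016023
MET	THR	-0.011582
MET	TRP	-0.012647
MET	TYR	-0.009395
MET	VAL	-0.012586
PHE	PHE	0.023890
PHE	PRO	-0.000382
PHE	SER	-0.012789
PHE	THR	-0.018951
PHE	TRP	-0.022051
PHE	TYR	-0.012160
PHE	VAL	-0.004802
PRO	PRO	-0.003652
PRO	SER	-0.012723
PRO	THR	-0.015219
PRO	TRP	-0.006094
PRO	TYR	0.011799
PRO	VAL	0.001106
SER	SER	-0.023172
SER	THR	0.010714
SER	TRP	0.011597
SER	TYR	-0.003170
SER	VAL	0.007165
THR	THR	-0.015674
THR	TRP	-0.010278
THR	TYR	0.010323
THR	VAL	0.010318
TRP	TRP	-0.007919
TRP	TYR	-0.011999
TRP	VAL	0.006687
TYR	TYR	-0.005422
TYR	VAL	-0.014985
VAL	VAL	-0.000304
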