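gene_symbol	chromosome	tx_start	tx_end
AATF	1	1000000	1020000
ABCC1	2	1000000	1027919
AGT	3	1000000	1035838
AGTR1	4	1000000	1043757
AKR1A1	5	1000000	1051676
AKR7A2	6	1000000	1059595
AKR7A3	7	1000000	1067514
ALOX12	8	1000000	1075433
AOX1	9	1000000	1083352
ARNT	10	1000000	1091271
ATOX1	11	1000000	1099190
CAT	12	1000000	1107109
CCL5	13	1000000	1115028
CDKN1A	14	1000000	1022947
CHUK	15	1000000	1030866
COL1A1	16	1000000	1038785
CP	17	1000000	1046704
CRISP2	18	1000000	1054623
CYBA	19	1000000	1062542
CYGB	20	1000000	1070461
CYP1A1	21	1000000	1078380
CYP1A2	22	1000000	1086299
DHCR24	1	2000000	2094218
DHRS2	2	2000000	2102137
DUSP1	3	2000000	2110056
EGFR	4	2000000	2117975
EP300	5	2000000	2025894
EPHX1	6	2000000	2033813
EPHX2	7	2000000	2041732
EPX	8	2000000	2049651
ERCC1	9	2000000	2057570
FMO2	10	2000000	2065489
FOS	11	2000000	2073408
FOSL1	12	2000000	2081327
GCLC	13	2000000	2089246
GCLM	14	2000000	2097165
GLRX	15	2000000	2105084
GLRX2	16	2000000	2113003
GLRX3	17	2000000	2020922
GLRX5	18	2000000	2028841
GPX1	19	2000000	2036760
GPX2	20	2000000	2044679
GPX3	21	2000000	2052598
GPX4	22	2000000	2060517
GPX5	1	3000000	3068436
GPX6	2	3000000	3076355
GPX7	3	3000000	3084274
GPX8	4	3000000	3092193
GRB2	5	3000000	3100112
GSR	6	3000000	3108031
GSS	7	3000000	3115950
GSTCD	8	3000000	3023869
GSTK1	9	3000000	3031788
GSTM1	10	3000000	3039707
GSTM2	11	3000000	3047626
GSTM3	12	3000000	3055545
GSTM4	13	3000000	3063464
GSTM5	14	3000000	3071383
GSTO1	15	3000000	3079302
GSTO2	16	3000000	3087221
GSTP1	17	3000000	3095140
GSTT1	18	3000000	3103059
GSTT2	19	3000000	3110978
GSTZ1	20	3000000	3118897
HMOX1	21	3000000	3026816
HMOX2	22	3000000	3034735
HP	1	4000000	4042654
IDH1	2	4000000	4050573
INSR	3	4000000	4058492
JAK2	4	4000000	4066411
JUN	5	4000000	4074330
KEAP1	6	4000000	4082249
LPO	7	4000000	4090168
MAP2K1	8	4000000	4098087
MAPK14	9	4000000	4106006
MGST1	10	4000000	4113925
MGST2	11	4000000	4021844
MGST3	12	4000000	4029763
MPO	13	4000000	4037682
MSRA	14	4000000	4045601
MT2A	15	4000000	4053520
NAPRT1	16	4000000	4061439
NCF2	17	4000000	4069358
NDUFA12	18	4000000	4077277
NDUFA13	19	4000000	4085196
NDUFA6	20	4000000	4093115
NDUFS1	21	4000000	4101034
NDUFS2	22	4000000	4108953
NDUFS3	1	5000000	5116872
NDUFS4	2	5000000	5024791
NDUFS8	3	5000000	5032710
NFE2L2	4	5000000	5040629
NFKB1	5	5000000	5048548
NOS1	6	5000000	5056467
NOS2	7	5000000	5064386
NOS3	8	5000000	5072305
NOX3	9	5000000	5080224
NOX4	10	5000000	5088143
NOX5	11	5000000	5096062
NOXO1	12	5000000	5103981
NQO1	13	5000000	5111900
NQO2	14	5000000	5119819
OGG1	15	5000000	5027738
OXR1	16	5000000	5035657
PARK2	17	5000000	5043576
PARK7	18	5000000	5051495
PLA2G4A	19	5000000	5059414
PLCB1	20	5000000	5067333
PLCG1	21	5000000	5075252
PNKP	22	5000000	5083171
PPP2CB	1	6000000	6091090
PRDX1	2	6000000	6099009
PRDX2	3	6000000	6106928
PRDX3	4	6000000	6114847
PRDX5	5	6000000	6022766
PRDX6	6	6000000	6030685
PRKCA	7	6000000	6038604
PSEN1	8	6000000	6046523
PSMB5	9	6000000	6054442
PTGS1	10	6000000	6062361
PTGS2	11	6000000	6070280
PTK2B	12	6000000	6078199
PXDN	13	6000000	6086118
PYCR1	14	6000000	6094037
RAC1	15	6000000	6101956
RAC2	16	6000000	6109875
RELA	17	6000000	6117794
RIPK1	18	6000000	6025713
SCARA3	19	6000000	6033632
SEPP1	20	6000000	6041551
SLC23A2	21	6000000	6049470
SNCA	22	6000000	6057389
SOD1	1	7000000	7065308
SOD2	2	7000000	7073227
SOD3	3	7000000	7081146
SRXN1	4	7000000	7089065
STAT1	5	7000000	7096984
STK25	6	7000000	7104903
TGFBR2	7	7000000	7112822
TLR4	8	7000000	7020741
TP53	9	7000000	7028660
TPO	10	7000000	7036579
TXN	11	7000000	7044498
TXN2	12	7000000	7052417
TXNIP	13	7000000	7060336
TXNRD1	14	7000000	7068255
TXNRD2	15	7000000	7076174
UCP2	16	7000000	7084093
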