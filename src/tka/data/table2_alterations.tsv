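alterations	n_alterations	putative_alterations	target_full	target_achievable	target_extended
EPHA2 amp and MAPK11 amp and PDGFRB amp and MAPK15 amp and FLT3 amp and HIPK4 amp	6	EPHA2 amp and MAPK11 amp and PDGFRB amp and MAPK15 amp and FLT3 amp and HIPK4 amp	yes	yes	yes
KDR amp and KIT amp and PDGFRA amp and FRK over and HIPK4 over	5	KDR amp and KIT amp and PDGFRA amp and FRK over and HIPK4 over	yes	yes	yes
KDR mut and FLT4 mut and KDR amp and PDGFRA amp and KIT amp	5	KDR amp and PDGFRA amp and KIT amp	yes	yes	yes
KDR mut and DDR2 mut and HIPK4 mut and SLK mut and MKNK2 mut	5	-	no	no	no
BRAF amp and KIT amp and PDGFRA amp and STK10 mut	4	BRAF amp and KIT amp and PDGFRA amp	yes	yes	yes
PDGFRA amp and MAP3K19 mut (VUS-NMD) and TEK mut and PDGFRA over	4	PDGFRA amp and PDGFRA over	yes	yes	yes
MKNK2 mut and EPHA2 mut and DDR1 mut and BRAF mut	4	-	no	no	no
KDR amp and KIT amp and PDGFRA amp	3	KDR amp and KIT amp and PDGFRA amp	yes	yes	yes
FRK mut and PDGFRA amp and KIT amp	3	PDGFRA amp and KIT amp	yes	yes	yes
PDGFRA amp and MAP4K4 mut and MUSK over	3	PDGFRA amp and MUSK over	yes	yes	yes
FLT3 mut and EPHA2 over and MKNK2 over	3	EPHA2 over and MKNK2 over	yes	yes	yes
NTRK1 mut and FGFR4 mut and RAF1 over	3	RAF1 over	yes	yes	yes
RET mut and MAP2K5 mut and PDGFRA over	3	PDGFRA over	yes	yes	yes
NTRK1 mut and BRAF mut and MAP2K5 mut (VUS-NMD)	3	BRAF mut	yes	yes	yes
FLT4 mut and SLK over and MAP2K5 over	3	SLK over and MAP2K5 over	yes	no	yes
FGFR1 mut, MAPK9 mut and MAPK9 amp	3	MAPK9 amp	yes	no	yes
NTRK1 mut and FLT4 mut and KDR mut	3	-	no	no	no
FLT4 mut and BRAF mut and MAP3K19 mut (VUS-NMD)	3	-	no	no	no
PDGFRA amp and PDGFRA over	2	PDGFRA amp and PDGFRA over	yes	yes	yes
PDGFRA amp and ABL1::SZRD1 fusion	2	PDGFRA amp and ABL1::SZRD1 fusion	yes	yes	yes
MAPK9 amp and DDR2 mut	2	MAPK9 amp and DDR2 mut	yes	yes	yes
FGFR1 amp and FGFR4 amp	2	FGFR1 amp and FGFR4 amp	yes	yes	yes
NTRK1 mut and PDGFRA mut	2	PDGFRA mut	yes	yes	yes
EPHA2 mut and FGFR2 mut	2	FGFR2 mut	yes	yes	yes
CSFR1 mut and EPHA2 over	2	EPHA2 over	yes	yes	yes
KDR mut and FRK over	2	FRK over	yes	yes	yes
FRK mut and FRK over	2	FRK over	yes	yes	yes
HIPK4 over and MUSK over	2	HIPK4 over and MUSK over	yes	no	no
DDR1 mut and SLK over	2	SLK over	yes	no	no
FGFR2 mut and PDGFRB mut	2	-	no	no	no
FLT1 mut and FLT4 mut	2	-	no	no	no
FLT4 mut and DDR2 mut	2	-	no	no	no
KDR mut and KIT mut	2	-	no	no	no
FLT4 mut and TNIK mut	2	-	no	no	no
MKNK2 mut and MAP3K7 mut	2	-	no	no	no
MAP4K4 mut	1	-	no	no	no
PDGFRA over	1	PDGFRA over	yes	yes	yes
RAF1 amp	1	RAF1 amp	yes	yes	yes
PDGFRB amp	1	PDGFRB amp	yes	yes	yes
BRAF mut	1	BRAF mut	yes	yes	yes
MAPK9 over	1	MAPK9 over	yes	no	yes
MAPK9 amp	1	MAPK9 amp	yes	no	yes
FRK over	1	FRK over	yes	yes	yes
HIPK4 over	1	HIPK4 over	yes	no	no
CDK8 amp	1	CDK8 amp	yes	no	no
EPHA2 mut	1	-	no	no	no
DDR2 mut	1	-	no	no	no
FGFR1 mut	1	-	no	no	no
FGFR3 mut	1	-	no	no	no
FLT1 mut	1	-	no	no	no
KIT mut	1	-	no	no	no
PDGFRA mut	1	-	no	no	no
TEK mut	1	-	no	no	no
TEK mut	1	-	no	no	no
TEK mut	1	-	no	no	no
RET mut	1	-	no	no	no
TEK mut	1	-	no	no	no
TIE1 mut	1	-	no	no	no
CSFR1 mut	1	-	no	no	no
EPHA6 mut	1	-	no	no	no
MKNK2 mut	1	-	no	no	no
CSFR1 mut	1	-	no	no	no
DDR1 mut	1	-	no	no	no
EPHA8 mut	1	-	no	no	no
MAP3K19 mut	1	-	no	no	no
MAP3K19 mut	1	-	no	no	no
MAP3K19 mut	1	-	no	no	no
MAPK14 mut	1	-	no	no	no
MAPK15 mut	1	-	no	no	no
MAPK15 mut	1	-	no	no	no
MAPK9 mut	1	-	no	no	no
TNIK mut	1	-	no	no	no
TNIK mut	1	-	no	no	no
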