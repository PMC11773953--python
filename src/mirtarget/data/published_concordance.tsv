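mirna	dataset	cohort_context	direction	correlation_sign	gene
mir-335	GSE68742	SARC	down	negative	CFLAR
mir-335	GSE68742	SARC	down	negative	FIGN
mir-335	GSE68742	SARC	down	negative	MSRB3
mir-335	GSE68742	SARC	down	negative	SOD3
mir-335	GSE68742	SARC	down	negative	RGS2
mir-335	GSE68742	SARC	down	negative	SGK1
mir-335	GSE68742	SARC	down	negative	PMP22
mir-335	GSE68742	SARC	down	positive	CCDC3
mir-335	GSE68742	SARC	down	positive	LDB2
mir-335	GSE68742	SARC	down	positive	DZIP1
mir-335	GSE68742	SARC	down	positive	KLF2
mir-335	GSE68742	SARC	down	positive	CXCL12
mir-335	GSE68742	SARC	down	positive	NTRK3
mir-335	GSE68742	SARC	down	positive	PABPC5
mir-335	GSE68742	SARC	down	positive	RBMS3
mir-335	GSE68742	SARC	down	positive	RCBTB2
mir-335	GSE68742	SARC	down	positive	RUNX1T1
mir-335	GSE68742	SARC	up	negative	A2M
mir-335	GSE68742	SARC	up	negative	ACTA2
mir-335	GSE68742	SARC	up	negative	DUSP3
mir-335	GSE68742	SARC	up	negative	TNFSF10
mir-335	GSE68742	SARC	up	negative	SGCB
mir-335	GSE68742	SARC	up	negative	SPARCL1
mir-335	GSE68742	SARC	up	negative	SSFA2
mir-335	GSE68742	SARC	up	negative	FAS
mir-335	GSE68742	SARC	up	positive	EGR2
mir-335	GSE68742	SARC	up	positive	JDP2
mir-335	GSE68742	SARC	up	positive	PRICKLE1
mir-335	GSE68742	SARC	up	positive	LOC728392
mir-335	GSE68742	SARC	up	positive	MATN2
mir-335	GSE68742	SARC	up	positive	LMO2
mir-335	GSE9586	LUAD	down	negative	CD247
mir-335	GSE9586	LUAD	down	negative	DPYD
mir-335	GSE9586	LUAD	down	negative	F3
mir-335	GSE9586	LUAD	down	negative	LHFP
mir-335	GSE9586	LUAD	down	negative	PTX3
mir-335	GSE9586	LUAD	down	negative	MNDA
mir-335	GSE9586	LUAD	down	negative	MT1E
mir-335	GSE9586	LUAD	down	negative	MYL9
mir-335	GSE9586	LUAD	down	negative	SCD5
mir-335	GSE9586	LUAD	down	negative	SLFN11
mir-335	GSE9586	LUAD	down	positive	OSR2
mir-335	GSE9586	LUAD	up	negative	ADAM23
mir-335	GSE9586	LUAD	up	negative	CALD1
mir-335	GSE9586	LUAD	up	negative	CALHM2
mir-335	GSE9586	LUAD	up	negative	CTTNBP2NL
mir-335	GSE9586	LUAD	up	negative	DIXDC1
mir-335	GSE9586	LUAD	up	negative	DUSP3
mir-335	GSE9586	LUAD	up	negative	FBXL7
mir-335	GSE9586	LUAD	up	negative	GCC2
mir-335	GSE9586	LUAD	up	negative	GLI3
mir-335	GSE9586	LUAD	up	negative	HVCN1
mir-335	GSE9586	LUAD	up	negative	JAK1
mir-335	GSE9586	LUAD	up	negative	MCTP1
mir-335	GSE9586	LUAD	up	negative	SGCB
mir-335	GSE9586	LUAD	up	negative	RHOJ
mir-335	GSE9586	LUAD	up	negative	PCDHGA9
mir-192	GSE62951	LIHC	down	negative	E2F7
mir-192	GSE62951	LIHC	down	negative	KIF2C
mir-192	GSE62951	LIHC	down	negative	MTBP
mir-192	GSE62951	LIHC	down	negative	NCS1
mir-192	GSE62951	LIHC	down	negative	RAD54L
mir-192	GSE62951	LIHC	up	positive	KIF4A
mir-192	GSE69990	OV	down	negative	SERTAD2
mir-192	GSE69990	OV	down	positive	BIRC5
mir-192	GSE69990	OV	down	positive	EZH2
mir-192	GSE69990	OV	down	positive	PLK1
mir-26b	GSE12091	CESC	down	positive	C1S
mir-193b	GSE83690	SARC	down	positive	C9orf140
mir-193b	GSE83690	SARC	down	positive	CCNB2
mir-193b	GSE83690	SARC	down	positive	CENPA
mir-193b	GSE83690	SARC	down	positive	KIF23
mir-193b	GSE83690	SARC	down	positive	KIF2C
mir-193b	GSE83690	SARC	down	positive	NUSAP1
mir-193b	GSE83690	SARC	down	positive	TROAP
mir-193b	GSE25215	PAAD	up	positive	CCNB2
mir-193b	GSE25215	PAAD	up	positive	CDC25C
mir-193b	GSE25215	PAAD	up	positive	CENPO
mir-193b	GSE25215	PAAD	up	positive	KIF23
mir-193b	GSE25215	PAAD	up	positive	KIF2C
mir-193b	GSE25215	PAAD	up	positive	PTTG1
mir-193b	GSE25215	PAAD	up	positive	TROAP
mir-193b	GSE25215	PAAD	up	positive	TTK
mir-193b	GSE18510	SKCM	up	positive	BIRC5
mir-193b	GSE18510	SKCM	up	positive	KIF2C
mir-21	GSE136665	COAD	up	negative	ACADSB
mir-21	GSE136665	COAD	up	negative	NAP1L5
mir-21	GSE136665	COAD	up	positive	AKAP11
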