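class	rank	gene_id
LUNG	1	CCNJL
LUNG	2	ICAM1
LUNG	3	LAMP3
LUNG	4	LPCAT1
LUNG	5	NAPSA
LUNG	6	ROS1
LUNG	7	SFTA2
LUNG	8	SFTPA1
LUNG	9	SFTPA2
LUNG	10	SFTPB
STAD	1	BRI3BP
STAD	2	CCDC109A
STAD	3	CDC42EP1
STAD	4	GATA6
STAD	5	GNL3L
STAD	6	HIATL2
STAD	7	PIAS1
STAD	8	POU2F1
STAD	9	ZBTB7A
STAD	10	ZFPM1
COADREAD	1	C2orf89
COADREAD	2	CDH17
COADREAD	3	CDX1
COADREAD	4	CDX2
COADREAD	5	EPS8L3
COADREAD	6	GPA33
COADREAD	7	GPR35
COADREAD	8	HEPH
COADREAD	9	NOX1
COADREAD	10	VIL1
LIHC	1	AMBP
LIHC	2	APOB
LIHC	3	APOC2
LIHC	4	ASGR1
LIHC	5	ASGR2
LIHC	6	F2
LIHC	7	ITIH1
LIHC	8	PROC
LIHC	9	SERPINA10
LIHC	10	VTN
BRCA	1	C18orf45
BRCA	2	EFHD1
BRCA	3	GATA3
BRCA	4	IRX5
BRCA	5	LMX1B
BRCA	6	PRLR
BRCA	7	TBC1D9
BRCA	8	TFAP2A
BRCA	9	TRPS1
BRCA	10	XBP1
OV	1	BCAM
OV	2	C10orf41
OV	3	GPR27
OV	4	HOXD4
OV	5	KCNK15
OV	6	KLHL14
OV	7	WIT1
OV	8	WT1
OV	9	ZFP92
OV	10	ZNF503
CESC	1	C1orf14
CESC	2	C9orf53
CESC	3	CENPW
CESC	4	LOC642587
CESC	5	PSMC3IP
CESC	6	RASIP1
CESC	7	SERPINB3
CESC	8	SERPINB4
CESC	9	SMC1B
CESC	10	TCAM1P
UCEC	1	ASRGL1
UCEC	2	DLX5
UCEC	3	DLX6
UCEC	4	FLJ39739
UCEC	5	LOC442459
UCEC	6	LOC643387
UCEC	7	LYPLA2P1
UCEC	8	MSX1
UCEC	9	SOX17
UCEC	10	STX18
PAAD	1	CASR
PAAD	2	CTRB1
PAAD	3	CTRB2
PAAD	4	CUZD1
PAAD	5	FFAR1
PAAD	6	FOXL1
PAAD	7	INS
PAAD	8	PNLIPRP1
PAAD	9	PRSS3
PAAD	10	TRY6
BLCA	1	C10orf116
BLCA	2	FER1L4
BLCA	3	GRHL3
BLCA	4	KRT7
BLCA	5	LOC100188947
BLCA	6	PLA2G2F
BLCA	7	PPARG
BLCA	8	SNCG
BLCA	9	UPK1A
BLCA	10	UPK2
HNSC	1	BNC1
HNSC	2	CSDAP1
HNSC	3	GJB5
HNSC	4	KRT14
HNSC	5	KRT5
HNSC	6	KRT6A
HNSC	7	KRT6B
HNSC	8	PKP1
HNSC	9	PTTG3P
HNSC	10	SFN
THCA	1	APLP2
THCA	2	CTSB
THCA	3	DAPK2
THCA	4	HHEX
THCA	5	LCN12
THCA	6	MUC15
THCA	7	NKX2-1
THCA	8	NPC2
THCA	9	TSHR
THCA	10	ZBED2
PRAD	1	C17orf93
PRAD	2	HOXB13
PRAD	3	KLK2
PRAD	4	KLK3
PRAD	5	KLK4
PRAD	6	NKX3-1
PRAD	7	SLC45A3
PRAD	8	STEAP2
PRAD	9	TMPRSS2
PRAD	10	TRPV6
KIDNEY	1	C14orf105
KIDNEY	2	CNDP2
KIDNEY	3	DAB2
KIDNEY	4	FBXO17
KIDNEY	5	GALNT14
KIDNEY	6	PKD2
KIDNEY	7	SLC22A2
KIDNEY	8	SLC28A1
KIDNEY	9	SLC3A1
KIDNEY	10	TMEM140
BRAIN	1	BAALC
BRAIN	2	CACNG7
BRAIN	3	CTNND2
BRAIN	4	FEZ1
BRAIN	5	GPM6B
BRAIN	6	LRRC4B
BRAIN	7	MGC42105
BRAIN	8	PPP2R2B
BRAIN	9	REEP2
BRAIN	10	SYT11
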