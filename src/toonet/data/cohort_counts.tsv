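site	cancer_type	code	sample_size	percent
primary	Lung	LUAD + LUSC	914	12.25
primary	Gastroesophageal	STAD	415	5.56
primary	Colorectal	COAD + READ	604	8.10
primary	Liver	LIHC	294	3.94
primary	Breast	BRCA	1056	14.16
primary	Thyroid	THCA	500	6.70
primary	Cervical	CESC	258	3.46
primary	Brain	GBM + LGG	529	7.94
primary	Pancreatic	PAAD	142	1.90
primary	Ovary	OV	261	3.50
primary	Endometrial	UCEC	516	6.92
primary	Bladder	BLCA	301	4.03
primary	Kidney	KIRC + KIRP	748	10.03
primary	Head and Neck	HNSC	480	6.43
primary	Prostate	PRAD	379	5.08
metastatic	Breast	BRCA	7	35.00
metastatic	Cervical	CESC	2	10.00
metastatic	Colorectal	COAD + READ	1	5.00
metastatic	Head and Neck	HNSC	2	10.00
metastatic	Thyroid	THCA	8	40.00
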