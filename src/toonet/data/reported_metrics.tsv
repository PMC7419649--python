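cancer_type	sensitivity	precision
Lung	91.87	92.76
Gastroesophageal	94.89	96.33
Colorectal	98.06	96.88
Liver	97.99	98.80
Breast	98.43	97.98
Thyroid	99.38	99.58
Cervical	71.63	76.38
Brain	99.32	99.41
Pancreatic	91.76	94.63
Ovarian	97.55	97.15
Endometrial	95.54	94.85
Bladder	74.75	88.36
Kidney	98.42	98.54
Head and Neck	90.83	79.39
Prostate	100.00	100.00
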