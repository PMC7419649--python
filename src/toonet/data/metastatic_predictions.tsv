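sample_id	predicted_by_NN	predicted_by_logistic	true_label
TCGA-AC-A6IX-06A-11R-A32P-07	BRCA	BRCA	BRCA
TCGA-BH-A18V-06A-11R-A213-07	BRCA	BLCA	BRCA
TCGA-BH-A1ES-06A-12R-A24H-07	BRCA	LIHC	BRCA
TCGA-BH-A1FE-06A-11R-A213-07	KIDNEY	KIDNEY	BRCA
TCGA-E2-A15A-06A-11R-A12D-07	BRCA	BRCA	BRCA
TCGA-E2-A15E-06A-11R-A12D-07	BRCA	BRCA	BRCA
TCGA-E2-A15K-06A-11R-A12P-07	BRCA	BRCA	BRCA
TCGA-HM-A6W2-06A-22R-A33Z-07	UCEC	UCEC	CESC
TCGA-UC-A7PG-06A-11R-A42S-07	CESC	CESC	CESC
TCGA-NH-A8F7-06A-31R-A41B-07	COAD + READ	COADREAD	COAD + READ
TCGA-KU-A6H7-06A-21R-A31N-07	CESC	CESC	HNSC
TCGA-UF-A71A-06A-11R-A39I-07	LUNG	LUNG	HNSC
TCGA-DE-A4MD-06A-11R-A250-07	THCA	THCA	THCA
TCGA-EM-A2CS-06A-11R-A180-07	THCA	THCA	THCA
TCGA-EM-A2P1-06A-11R-A206-07	THCA	THCA	THCA
TCGA-EM-A3FQ-06A-11R-A21D-07	THCA	THCA	THCA
TCGA-EM-A3SU-06A-11R-A22U-07	THCA	THCA	THCA
TCGA-J8-A3O2-06A-11R-A23N-07	THCA	THCA	THCA
TCGA-J8-A3YH-06A-11R-A23N-07	THCA	THCA	THCA
TCGA-J8-A4HW-06A-11R-A250-07	THCA	THCA	THCA
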