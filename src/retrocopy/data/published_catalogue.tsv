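sample	cancer_type	pseudogene	exons	full_length	insertion_site	target_site_dup	internal_inversion
PD7354c	Lung	ATP11B	19-30	No	Unmapped	NA	No
PD7354h	Lung	ANLN	15-24	No	Intergenic	12 bp	Yes
PD7354h	Lung	KTN1	11-14; 44	No	Intron 15 PSD3	7 bp	Yes
PD7354h	Lung	UBAP2L	21-26	No	Intergenic	18 bp	No
PD7354h	Lung	MYBL2	11-14	No	Intergenic	NA	No
PD7354h	Lung	AKR1C3	1-9	No	Unmapped	NA	No
PD7354k	Lung	APP	14-16	No	Unmapped	NA	No
PD7354k	Lung	CD55	1-11	Yes	Unmapped	NA	No
PD7354k	Lung	CENPF	13-20	No	Intergenic	None	No
PD7354k	Lung	DDX46	6-12	No	Unmapped	NA	No
PD7354k	Lung	PSAP	5-14	No	Unmapped	NA	No
PD7354k	Lung	S100A11	1-3	Yes	Upstream CLMP	None	No
PD7354r	Lung	FMO3	5; 8-9	No	Upstream TIPIN	10 bp	No
PD7354r	Lung	HDAC1	6-14	No	Intergenic	9 bp	No
PD7354r	Lung	HDDC2	1-6	Yes	Rearrangement	None	No
PD7354r	Lung	ODC1	8-12	No	Intergenic	5 bp	No
PD7355a	Lung	GOT1	5-9	No	Intron 1 CDH12	None	No
PD7356c	Lung	AKR1C1	6-9	No	Intergenic	14 bp	No
PD7356c	Lung	MYH9	28-41	No	Intergenic	10 bp	Yes
PD7356c	Lung	RCOR1	5-8; 12	No	Intron 3 ESR1	16 bp	Yes
PD7356c	Lung	TSPAN6	1-4; 6-8	Yes	Intron 3 RIT2	14 bp	No
PD7356i	Lung	FOPNL	1-5	Yes	Intron 11 SND1	10 bp	No
PD4864b	Lung	FNTA	1-9	No	Intergenic	NA	No
PD4864b	Lung	KRT14	1-8	No	Unmapped	NA	No
PD4861b	Lung	ARHGEF9	4-10	No	Intergenic	None	No
PD4861b	Lung	HNRNPD	4-9	No	Intron 1 RAB8B	9 bp	No
PD6377a	Gastric	SLC12A1	25-27	No	Intron 15 ADAMTS3	NA	Yes
PD6384a	Gastric	POF1B	1-11; 17	No	Intergenic	NA	Yes
PD6388a	Gastric	MRPL11	1-5	Yes	Intron 1 ABCA13	15 bp	No
PD7261a	Colorectal	HDAC1	1-14	Yes	Intron 1 RASA2	NA	No
PD9061a	Colorectal	CAST	18-29	No	Intergenic	NA	No
PD6022a	Gastric	ARF4	1-6	Yes	Unmapped	NA	No
PD6037a	Cholangiocarcinoma	CSDE1	7-16	No	Unmapped	NA	No
PD4226a	Breast	THUMPD2	8-10	No	Unmapped	NA	Yes
PD4226a	Breast	COBL	10-13	No	Unmapped	NA	No
PD6368a	Chondrosarcoma	SEP15	1-5	Yes	3' UTR WARS2	NA	No
LB771-HNC	Cell line (H&N)	KRT6A	1-3; 4-9	No	3' UTR MLL	17 bp	Yes
LB771-HNC	Cell line (H&N)	KIF18A	7-14	No	3' UTR BIN3, KIAA1967	None	No
NCI-H2009	Cell line (lung)	C9orf41	3-8; 8	No	Intergenic	17 bp	Yes
NCI-H2009	Cell line (lung)	PTPN12	12-17	No	Exon 1 MGA	None	No
NCI-H2009	Cell line (lung)	IBTK	1-29	Yes	Intergenic	None	No
NCI-H2087	Cell line (lung)	ARPC5	1-4	Yes	Intergenic	16 bp	No
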