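subtype	gene
1	MGP
1	PIP
1	SCGB2A2
1	MUCL1
1	GSTP1
1	HLA-DRA
1	CD74
1	LDHB
1	TFF3
1	SLPI
1	APOD
1	PPP1R1B
1	PPP1R14C
1	FITM2
1	S100P
1	RN7SL56P
1	SEPP1
1	AGR2
1	MRPL45
1	TFF1
1	RBP1
1	PLEKHA5
1	CEACAM6
1	SNCG
1	MIEN1
1	TM4SF1
1	MT1G
1	MGST1
1	RP11-658F2.8
1	AGR3
1	HLA-B
1	GSTM3
1	HLA-A
1	MDK
1	CLU
1	ARHGDIB
1	ORMDL3
1	TMEM45A
1	TCEAL1
1	CISD3
1	AZGP1
2	MGP
2	CTTN
2	SSR4
2	NDUFC2
2	CLU
2	S100A11
2	NDUFS5
2	AGR2
2	MGST1
2	TFF3
2	SRP9
2	EGR1
2	DYNLT1
2	TXNDC17
2	MIF
2	MT1X
2	SOX4
2	PPFIA1
2	AZGP1
2	HLA-DRA
2	PSENEN
2	KRT19
2	CD9
2	HLA-B
2	TM4SF1
2	KRT7
2	SCGB2A2
2	MT2A
2	S100A16
2	ERGIC3
2	KRTCAP2
2	PPAPDC1B
2	UQCRQ
2	EFNA1
2	ARF4
2	CD24P4
2	PPA1
2	CD63
2	POLR2K
2	ATRAID
2	CD46
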