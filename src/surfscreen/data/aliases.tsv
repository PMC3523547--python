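alias	canonical
CD146/MCAM	MCAM
CD279/PD1	PDCD1
PD1	PDCD1
CD42c	GP1BB
CD42C	GP1BB
CD107a	LAMP1
CD107A	LAMP1
CD45-AP	PTPRCAP
SIPR4	S1PR4
DAGLBETA	DAGLB
ALS2CR4	TMEM237
CD271/NGFR	NGFR
CD362/SDC2	SDC2
CD85k/LILRB4	LILRB4
CD85K/LILRB4	LILRB4
MSR1/CD204	MSR1
CSF1R/CD115	CSF1R
IGF2R/CD222	IGF2R
FZD10/CD350	FZD10
MS4A4A/CD20L1	MS4A4A
MS4A6A/CD20L3	MS4A6A
LRRN6A/LINGO1	LINGO1
CADM4/IGSF4C	CADM4
CADM1/IGSF4A	CADM1
LPPR3/PRG2	PRG2
LPPR1/PRG3	PRG3
LPPR5/PRG5	PRG5
CD301	CLEC10A
CD30	TNFRSF8
CD185	CXCR5
CD73	NT5E
CD155	PVR
CD112	PVRL2
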