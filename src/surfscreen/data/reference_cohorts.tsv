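disease	n_samples	hits_above_10
Pre-B_ALL	9	120
ARMS	12	62
ASPS	7	52
GBM	7	52
NBL-MYCNA	24	44
STS	6	38
OS	17	31
HBL	7	24
EWS	19	22
ERMS	9	16
NBL	15	4
DSRCT	8	0
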