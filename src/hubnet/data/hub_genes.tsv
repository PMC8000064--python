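gene	direction
IL6	up
VEGFA	up
SRC	up
APP	up
CXCL8	up
IDH1	up
SQSTM1	up
EGFR	up
PTGS2	up
ALDOA	up
NCL	down
RPS3	down
UBA52	down
DNMT1	down
CCNB1	down
EZH2	down
PLK1	down
POLR2H	down
UBE2C	down
TYMS	down
PCNA	down
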