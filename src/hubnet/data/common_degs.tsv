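gene	category
ACSL3	up
ACTA2	up
ADGRG1	up
AKR1B1	up
ASAP2	up
ASS1	up
ATP2B4	up
BAALC	up
BHLHE40	up
CALD1	up
CCDC92	up
CLIC4	up
CSF3	up
CXCL8	up
FAM65A	up
FGF2	up
HIST2H2BE	up
HLA-B	up
HLA-DPA1	up
HLA-DRA	up
IDH1	up
IER3	up
IGFBP7	up
IL1B	up
IL6	up
INSIG1	up
KDELR3	up
LRRN3	up
MLLT11	up
MSMO1	up
MTSS1	up
NAMPT	up
NME4	up
NOTCH3	up
PAMR1	up
PDGFRB	up
PHKB	up
PPP1R3C	up
PTGS2	up
RCAN1	up
RFTN2	up
RHBDF1	up
RND3	up
RRAD	up
RSPO3	up
SEZ6L2	up
SH3BGRL	up
SMARCA1	up
SNX7	up
SPP1	up
SRPX2	up
SYNC	up
SYNDIG1	up
TAP1	up
TFPI2	up
TGM2	up
TMCO3	up
TMEM171	up
TMEM98	up
TOX2	up
TSPAN13	up
VAT1L	up
EIF6	down
NTSR1	down
IMP4	down
RPPH1	down
TOP3A	down
LYAR	down
THOC5	down
CXADR	down
FOXR2	down
DHRS11	down
DBNDD2	down
DDX27	down
DNAAF3	down
ALKBH2	down
IPO4	down
DUS3	down
MRPL12	down
PRPF19	down
INTS1	down
DDX18	down
FERMT3	down
EMG1	down
SNU13	down
SERPINB7	down
RPS19BP1	down
UBL7	down
RPS21	down
CCL26	down
SLC43A3	down
IL13RA2	down
NHP2	down
SNAPC4	down
GRWD1	down
PHB2	down
MRTO4	down
PDSS1	down
SPOUT1	down
DNLZ	down
GPATCH4	down
CCL20	down
EIF2B2	down
ZNF593	down
NOP16	down
NUDT14	down
MCM10	down
SLIRP	down
RRS1	down
KLRG1	down
ATF5	down
CDK4	down
COQ3	down
GEMIN4	down
GEMIN6	down
FTSJ3	down
PAK1IP1	down
MRPS26	down
NTS	down
TOMM22	down
EXOSC5	down
ATAD3A	down
GAR1	down
RPF2	down
TEAD4	down
PPAN	down
UBE2G2	down
C9orf142	down
PRPF4	down
PPIH	down
RPL36	down
TTLL12	down
WDR46	down
PSMG3	down
PRIM1	down
CSTF2	down
TOMM6	down
AHSA1	down
TFB2M	down
SLC5A6	down
NOP56	down
TIMM10	down
C10orf2	down
CLPTM1L	down
DPH2	down
C19orf48	down
FEN1	down
UBA52	down
FARSA	down
ELOF1	down
S100A2	down
NOL6	down
STOML2	down
ADSL	down
CHCHD10	down
POLR2H	down
PA2G4	down
E2F2	down
PRKAR1B	down
LBHD1	down
PRELID1	down
MRPL21	down
EXOSC4	down
TRIML2	down
NPM3	down
SNORD104	down
EBNA1BP2	down
WDR18	down
EIF3K	down
STC2	down
POLD1	down
SFXN4	down
SNORA67	down
METTL17	down
ATIC	down
EIF3G	down
SDCCAG3	down
MAGEB2	down
PNP	down
HCLS1	down
NDUFB9	down
DHRS2	down
CDC25A	down
ESM1	down
CRABP2	both
EDNRA	both
GJB2	both
IGFBP5	both
MATN2	both
MFAP4	both
NREP	both
OLFML2A	both
PCOLCE	both
PDGFRA	both
RGS2	both
SERPINB2	both
TGFB3	both
TIMP2	both
TRIM9	both
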