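growth_factors	Growth factors	HBEGF	VEGFA	EGFR	PDGFRB	FGF13	FGF2	TFPI	TFPI2	TGFA	TGIF1	WNT5A	BDNF	NRG1	TIMP1	PDGFRA	TGFB3
cytokines	Cytokines	CSF3	NAMPT	CCL3	IL6	CXCL2	CXCL8	GREM1	IL11	IL36RN	LIF	CLCF1	CCL3L3	IL36B	IL1B	IL1A	SPP1	IL1R1	NRG1	EREG
bmps	Bone morphogenetic proteins	BMP6	GREM1	NBL1	TWSG1
proto_oncogenes	Proto-oncogenes	FYN	MLLT11	PDGFRB	BCL6	SRC	CBLB	CRKL
gbm_genes	Genes involved in GBM	ESM1	PDGFRA	TGFB3
receptor_ligand_pairs	Receptor-ligand pairs	CD44-SPP1	CD44-HBEGF	CD44-FGF2	F3-IL6	F3-TFPI	IL6ST-CLCF1	IL6ST-IL6	IL6ST-LIF	IL6ST-IL11	ITGB1-SPP1	ITGB1-THBS1	ITGB1-VEGFA	NRP2-VEGFA	PLAUR-SERPINE1	EGFR-EREG	EGFR-FGF13	EGFR-HBEGF	EGFR-TGFA	EGFR-VEGFA
glycosyl_transferases	Enzymes (glycosyl transferases)	GBE1	PLOD2	HAS1	ST3GAL1	EDEM1
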