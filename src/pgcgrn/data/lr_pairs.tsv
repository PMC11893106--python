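pair_id	ligand	receptor	pathway_label
BMP2_BMR1A_AVR2B	Bmp2	Bmpr1a;Acvr2b	BMP
WNT4_FZD1_LRP6	Wnt4	Fzd1;Lrp6	WNT
DHH_PTCH1	Dhh	Ptch1	HH
KITL_KIT	Kitl	Kit	KIT
GDF9_BMPR2	Gdf9	Bmpr2	BMP
INHA_ACVR1B	Inha	Acvr1b	INHIBIN
FGF9_FGFR2	Fgf9	Fgfr2	FGF
IGF1_IGF1R	Igf1	Igf1r	IGF
JAG1_NOTCH1	Jag1	Notch1	NOTCH
PDGFA_PDGFRA	Pdgfa	Pdgfra	PDGF
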