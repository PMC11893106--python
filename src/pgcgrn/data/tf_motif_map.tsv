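motif_id	tf_name	gene_id
MA0815.1	TFAP2C	Tfap2c
MA0632.2	TCFL5	Tcfl5
MA0146.2	ZFX	Zfx
MA0801.1	MGA	Mga
MA1535.1	NR6A1	Nr6a1
MA0480.1	FOXO1	Foxo1
MA0628.1	POU6F1	Pou6f1
MA0073.1	RREB1	Rreb1
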