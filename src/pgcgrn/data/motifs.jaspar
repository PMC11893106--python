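>MA0815.1	TFAP2C
A  [   5   5   5   5   5  85   5   5   5  85 ]
C  [   5  85  85   5   5   5   5   5  85   5 ]
G  [  85   5   5   5  85   5  85  85   5   5 ]
T  [   5   5   5  85   5   5   5   5   5   5 ]
>MA0632.2	TCFL5
A  [  85  85   5  85   5   5   5   5   5   5 ]
C  [   5   5  85   5  85   5   5   5   5   5 ]
G  [   5   5   5   5   5  85   5  85   5   5 ]
T  [   5   5   5   5   5   5  85   5  85  85 ]
>MA0146.2	ZFX
A  [   5  85   5   5   5   5   5  85   5   5 ]
C  [   5   5   5   5  85  85   5   5   5  85 ]
G  [   5   5  85  85   5   5   5   5  85   5 ]
T  [  85   5   5   5   5   5  85   5   5   5 ]
>MA0801.1	MGA
A  [  85   5   5   5   5   5   5  85  85  85 ]
C  [   5   5   5   5   5   5   5   5   5   5 ]
G  [   5  85  85   5  85   5  85   5   5   5 ]
T  [   5   5   5  85   5  85   5   5   5   5 ]
>MA1535.1	NR6A1
A  [   5   5  85  85   5   5   5   5  85   5 ]
C  [   5  85   5   5   5   5   5  85   5   5 ]
G  [   5   5   5   5  85  85   5   5   5  85 ]
T  [  85   5   5   5   5   5  85   5   5   5 ]
>MA0480.1	FOXO1
A  [   5   5   5   5   5   5  85   5  85   5 ]
C  [   5   5   5   5   5   5   5  85   5   5 ]
G  [   5   5  85   5   5   5   5   5   5   5 ]
T  [  85  85   5  85  85  85   5   5   5  85 ]
>MA0628.1	POU6F1
A  [   5  85   5   5   5   5  85  85   5   5 ]
C  [   5   5   5   5  85   5   5   5   5   5 ]
G  [   5   5   5  85   5   5   5   5   5  85 ]
T  [  85   5  85   5   5  85   5   5  85   5 ]
>MA0073.1	RREB1
A  [   5   5   5   5  85  85  85   5   5  85 ]
C  [  85  85  85  85   5   5   5  85  85   5 ]
G  [   5   5   5   5   5   5   5   5   5   5 ]
T  [   5   5   5   5   5   5   5   5   5   5 ]
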