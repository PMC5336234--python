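gene	gene_id	chromosome
Ciona_1	ENSCING00000003151	Chr2
BEST3	ENSCING00000006827	Chr2
CNOT2	ENSCING00000006804;ENSCING00000021615	Chr2
CCT2	ENSCING00000005347	Chr7
PTPRR	ENSCING00000000420	Chr9
LGR5	ENSCING00000018199	Chr3
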