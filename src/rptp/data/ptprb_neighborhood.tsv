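genome	anchor	gene	chromosome	start
human	PTPRB	CCT2	chr12	69577135
human	PTPRB	LRCC10	chr12	69761778
human	PTPRB	BEST3	chr12	69674810
human	PTPRB	MYRFL	chr12	69808128
human	PTPRB	CNOT2	chr12	70243935
human	PTPRB	KCNMB4	chr12	70366259
human	PTPRB	PTPRR	chr12	70636932
human	PTPRB	LGR5	chr12	71504045
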