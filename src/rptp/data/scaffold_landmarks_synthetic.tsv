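scaffold	landmark	position
FN3_ref	W	20
FN3_ref	G	25
FN3_ref	Y	30
PTP_ref	WPD	93
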