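>FN3_ref synthetic FN3 reference scaffold
APSPTNLKVTDVTSTSLTLSWDAPAGVTNHYRITGLKPGTEYEVSVSAVNGAGEGPPSEP
VSFKTLAPAEP
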