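>PTP_ref synthetic PTP-domain reference scaffold
FSRIDANRAENRYKNILPYDWSRVPLKPIDEAPGSDYINASYIDGYKEKNKFIAAQGPKE
ETVNDFRMIEQNVEVIVMLTNLVERGRRKCDQYWPDQGSPLYGNIRVTLEDTRELATYTL
RTFQVSKNGHSETRTVKQFHFTSPNEDHGVPSAVDLVSFYRELRA
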