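source	target	weight	type
AIBL	RIML	1	gap
AIBR	RIMR	1	gap
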