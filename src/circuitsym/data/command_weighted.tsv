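source	target	weight	type
AVBL	AVBR	1	gap
AVBL	RIBL	2	gap
AVBL	RIBR	2	gap
AVBR	RIBL	2	gap
AVBR	RIBR	2	gap
RIBL	RIBR	1	gap
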