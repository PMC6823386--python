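source	target	weight	type
AVBL	AVBR	1	gap
AVBL	RIBL	1	gap
AVBL	RIBR	1	gap
AVBL	DB5	1	gap
AVBL	DB6	1	gap
AVBL	DB7	1	gap
AVBL	VB10	1	gap
AVBL	VB11	1	gap
AVBL	VB2	3	gap
AVBL	DB3	2	gap
AVBL	DB2	1	gap
AVBL	VB1	4	gap
AVBL	DB1	3	gap
AVBL	VB4	2	gap
AVBL	VB5	1	gap
AVBL	VB6	4	gap
AVBL	VB3	6	gap
AVBL	VB7	6	gap
AVBL	VB8	7	gap
AVBL	VB9	7	gap
AVBR	RIBL	1	gap
AVBR	RIBR	1	gap
AVBR	DB5	1	gap
AVBR	DB6	1	gap
AVBR	DB7	1	gap
AVBR	VB10	1	gap
AVBR	VB11	1	gap
AVBR	VB2	3	gap
AVBR	DB3	2	gap
AVBR	DB2	1	gap
AVBR	VB1	4	gap
AVBR	DB1	3	gap
AVBR	VB4	2	gap
AVBR	VB5	1	gap
AVBR	VB6	4	gap
AVBR	VB3	6	gap
AVBR	VB7	6	gap
AVBR	VB8	7	gap
AVBR	VB9	7	gap
RIBL	RIBR	1	gap
VB2	DB3	1	gap
VB2	VB1	1	gap
VB2	VB6	2	gap
DB3	DB2	1	gap
DB3	VB5	2	gap
DB2	VB1	1	gap
DB2	VB4	2	gap
VB1	DB1	2	gap
DB1	VB4	1	gap
DB1	VB6	1	gap
VB4	VB5	1	gap
VB5	VB6	1	gap
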