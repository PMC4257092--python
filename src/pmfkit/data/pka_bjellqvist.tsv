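# Bjellqvist pKa set (ProtParam convention).
# group: SIDE_CHAIN, N_TERM or C_TERM; residue: one-letter code or DEFAULT
# sign: ACID (deprotonation yields -1) or BASE (protonation yields +1)
group	residue	pka	sign
SIDE_CHAIN	D	4.05	ACID
SIDE_CHAIN	E	4.45	ACID
SIDE_CHAIN	C	9.00	ACID
SIDE_CHAIN	Y	10.00	ACID
SIDE_CHAIN	H	5.98	BASE
SIDE_CHAIN	K	10.00	BASE
SIDE_CHAIN	R	12.00	BASE
N_TERM	DEFAULT	7.50	BASE
N_TERM	A	7.59	BASE
N_TERM	M	7.00	BASE
N_TERM	S	6.93	BASE
N_TERM	P	8.36	BASE
N_TERM	T	6.82	BASE
N_TERM	V	7.44	BASE
N_TERM	E	7.70	BASE
C_TERM	DEFAULT	3.55	ACID
C_TERM	D	4.55	ACID
C_TERM	E	4.75	ACID
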