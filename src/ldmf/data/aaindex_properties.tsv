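property_id	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
KYTJ820101	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
GRAR740103	31.0	55.0	54.0	83.0	132.0	3.0	96.0	111.0	119.0	111.0	105.0	56.0	32.5	85.0	124.0	32.0	61.0	84.0	170.0	136.0
KLEP840101	0.0	0.0	-1.0	-1.0	0.0	0.0	0.0	0.0	1.0	0.0	0.0	0.0	0.0	0.0	1.0	0.0	0.0	0.0	0.0	0.0
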