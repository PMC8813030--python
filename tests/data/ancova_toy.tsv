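y	group	age
3	A	20
5	A	24
4	A	28
7	B	22
8	B	26
9	B	30
12	C	21
11	C	25
13	C	29
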