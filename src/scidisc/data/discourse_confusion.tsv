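	problem	fact	hypothesis	goal	method	result	implication
problem	0	0	0	0	0	2	0
fact	1	14	2	2	2	26	6
hypothesis	0	2	12	5	3	6	8
goal	0	0	0	18	9	2	1
method	0	4	0	1	66	26	1
result	1	7	2	0	8	147	17
implication	0	3	1	0	2	7	31
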