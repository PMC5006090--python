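	MI:0018	MI:0019	MI:0096	MI:0416	MI:0663
MI:0018	25	29	3	0	0
MI:0019	0	321	9	0	2
MI:0096	1	53	71	0	0
MI:0416	0	26	0	4	4
MI:0663	0	20	0	3	10
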