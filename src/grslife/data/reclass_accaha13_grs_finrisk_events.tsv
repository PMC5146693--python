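old	0-7.5%	7.5-10%	10-20%	20-100%
0-7.5%	118	16	17	1
7.5-10%	20	14	29	6
10-20%	15	29	104	60
20-100%	0	0	15	73
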