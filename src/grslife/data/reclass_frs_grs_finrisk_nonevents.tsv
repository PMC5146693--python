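old	0-7.5%	7.5-10%	10-20%	20-100%
0-7.5%	9456	197	119	4
7.5-10%	346	178	195	17
10-20%	277	266	659	220
20-100%	1	12	97	108
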