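old	0-7.5%	7.5-10%	10-20%	20-100%
0-7.5%	110	21	19	2
7.5-10%	22	12	28	4
10-20%	22	24	108	78
20-100%	0	2	17	48
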