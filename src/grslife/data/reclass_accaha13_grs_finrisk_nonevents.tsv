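old	0-7.5%	7.5-10%	10-20%	20-100%
0-7.5%	9470	195	127	6
7.5-10%	361	162	170	8
10-20%	264	246	651	211
20-100%	2	10	112	157
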