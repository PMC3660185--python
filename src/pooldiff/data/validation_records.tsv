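gene	position	min_reads_pool	di_454	di_validation	di_validation_alt
RNF6	Chr1:48509942	13	0.92	0.69	0.56
RB1	Chr1:56558186	9	1.00	0.81	0.50
ESD	Chr1:57059422	12	0.92	0.63	0.38
ESD	Chr1:57059472	11	0.91	0.75	0.43
XPOT	Chr1A:32952256	10	0.94	0.19
ADCYAP1R1	Chr2:3348189	8	0.92	0.00
RNMT	Chr2:101951215	13	0.93	0.19
RNMT	Chr2:101951219	12	0.92	0.13
BAI3	Chr3:86028013	9	0.92	0.06
ENSTGUG00000005084	Chr5:3850065	18	0.91	0.88	0.88
FADS3	Chr5:6375371	30	0.95	0.88	0.94
FADS3	Chr5:6375565	25	0.96	0.94	0.94
FADS3	Chr5:6375583	22	0.96	0.75	0.69
SORD	Chr10:3477546	15	0.94	0.00
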