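word	group	hsap_C_percent	dmel_C_percent
CG	context_high_bias_hsap	-76.37	-5.93
ATAG	context_high_bias_hsap	-0.79	4.38
ATTG	context_high_bias_hsap	-7.07	-2.35
ACAA	context_high_bias_hsap	1.62	3.75
TG	derived_high_bias_hsap	20.10	10.67
ACAG	derived_high_bias_hsap	1.51	-4.94
ACTG	derived_high_bias_hsap	-2.07	-0.46
CCAA	derived_high_bias_hsap	-6.17	-1.61
CCAC	context_high_bias_dmel	0.19	1.52
CACC	context_high_bias_dmel	1.18	-4.24
CCCA	context_high_bias_dmel	5.63	0.09
GCCA	context_high_bias_dmel	-2.77	3.63
ACC	context_high_bias_dmel	2.28	-2.39
CCA	context_high_bias_dmel	14.82	9.90
CCCC	derived_high_bias_dmel	-5.10	2.19
GCCC	derived_high_bias_dmel	1.66	-1.41
CCC	derived_high_bias_dmel	-12.66	-7.78
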