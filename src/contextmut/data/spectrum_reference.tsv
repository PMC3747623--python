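species	substitution	fraction
dmel	A>C	0.044
dmel	T>G	0.047
dmel	C>G	0.047
dmel	G>C	0.048
dmel	A>T	0.057
dmel	T>A	0.058
dmel	A>G	0.063
dmel	T>C	0.064
dmel	G>T	0.118
dmel	C>A	0.121
dmel	C>T	0.166
dmel	G>A	0.167
hsap	A>T	0.031
hsap	T>A	0.031
hsap	A>C	0.037
hsap	T>G	0.038
hsap	C>G	0.051
hsap	G>C	0.051
hsap	G>T	0.058
hsap	C>A	0.058
hsap	T>C	0.118
hsap	A>G	0.118
hsap	C>T	0.204
hsap	G>A	0.204
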