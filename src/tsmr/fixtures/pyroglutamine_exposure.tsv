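SNP	EA	NEA	EAF	BETA	SE	P	N
rs715	C	T	0.286	-0.036	0.004	2.46E-16	7354
rs17279437	A	G	0.095	0.059	0.006	1.25E-20	7354
rs11613331	A	G	0.553	0.037	0.004	2.23E-25	7354
rs1600760	A	T	0.663	-0.022	0.004	5.12E-09	7354
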