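SNP	EA	NEA	EAF	BETA	SE	P	N
rs11613331	A	G	NA	-0.024	0.013	0.055	1299010
rs1600760	A	T	NA	-0.002	0.013	0.891	1299010
rs17279437	A	G	NA	-0.067	0.023	0.004	1299010
rs715	C	T	NA	0.015	0.014	0.289	1299010
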