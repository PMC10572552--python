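SNP	EA	OA	EAF	BETA	SE	P	N
rs11206510	T	C	NA	-0.0035	0.0034	0.315	27386
rs11591147	G	T	NA	-0.0366	0.0102	3e-4	27386
rs2479409	G	A	NA	-0.0031	0.0028	0.274	27386
rs45448095	C	T	NA	0.0003	0.0038	0.928	27386
rs499718	T	C	NA	0.0026	0.0035	0.453	27386
rs557435	A	G	NA	0.0043	0.0034	0.209	27386
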