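SNP	EA	OA	EAF	BETA	SE	P	N
rs11206510	T	C	NA	-0.051	0.009	8.98e-8	3290
rs11591147	G	T	NA	-0.315	0.037	1.94e-17	3290
rs2479409	G	A	NA	-0.052	0.009	7.41e-9	3290
rs45448095	C	T	NA	-0.085	0.012	4.40e-12	3290
rs499718	T	C	NA	0.062	0.012	7.81e-8	3290
rs557435	A	G	NA	0.050	0.010	2.22e-7	3290
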