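codon	aa	frac_enriched	dev_orfeome	dev_highphi	dev_cai	dev_tai
GGA	G	0.857	-0.024	-0.240	-0.248	-0.146
GAT	D	0.857	0.151	0.020	-0.144	-0.195
CCT	P	0.857	0.060	-0.052	-0.206	-0.130
CCG	P	0.857	-0.126	-0.245	-0.248	-0.058
CCA	P	0.857	0.157	0.522	0.695	0.351
GAC	D	0.786	-0.151	-0.020	0.144	0.195
GGT	G	0.714	0.205	0.678	0.725	-0.008
GGC	G	0.714	-0.053	-0.197	-0.230	0.302
GAG	E	0.714	-0.201	-0.386	-0.484	-0.184
ACG	T	0.714	-0.112	-0.238	-0.247	-0.160
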