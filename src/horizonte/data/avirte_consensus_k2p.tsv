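# Published pairwise Kimura 2-parameter distances (substitutions/site,
# uniform rates, pairwise deletion) between the eleven full-length AviRTE
# consensus sequences reconstructed from bird and filarial-nematode host
# genomes.  Lower triangle; taxon codes are host-genome abbreviations.
taxon	apaVit	araMac	bucRhi	calAnn	gymRuf	loaLoa	manVit	melUnd	mesUni	oreMel	tinGut
apaVit
araMac	0.087
bucRhi	0.078	0.055
calAnn	0.080	0.099	0.089
gymRuf	0.090	0.112	0.105	0.107
loaLoa	0.109	0.135	0.131	0.134	0.146
manVit	0.116	0.139	0.131	0.138	0.133	0.169
melUnd	0.101	0.065	0.074	0.116	0.132	0.152	0.151
mesUni	0.035	0.091	0.084	0.084	0.090	0.114	0.118	0.108
oreMel	0.076	0.094	0.086	0.009	0.104	0.129	0.135	0.114	0.081
tinGut	0.047	0.086	0.077	0.081	0.088	0.103	0.117	0.102	0.051	0.078
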