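rsid	effect_allele	other_allele	effect_size	genetic_model	locus_label	source
rs11672691	G	A	1.12	additive	ATP5SL/CEACAM21 19q13	OR per G allele, aggressive vs controls
rs11704416	G	C	0.94	additive	TNRC6 22q13	OR per G allele, aggressive vs controls
rs4054823	T	C	1.13	additive	17p12	OR per T allele, aggressive vs non-aggressive
rs10788165	T	G	1.34	recessive	10q21.12	OR TT vs GG/GT, aggressive vs controls
rs10749408	T	C	1.26	recessive	10q21.12	OR TT vs CT/CC, aggressive vs controls
rs11199874	G	A	1.42	recessive	10q21.12	OR GG vs AG/AA, aggressive vs controls
rs4775302	A	G	1.41	dominant	15q21.1	OR AG/AA vs GG, aggressive vs controls
rs1994198	T	C	1.34	dominant	15q21.1	OR CT/TT vs CC, aggressive vs controls
rs1571801	C	A	1.36	dominant	DAB2IP 9q33.2	OR AC/CC vs AA, aggressive vs controls
rs6497287	C	T	1.46	dominant	HERC2 15q13	OR TC/CC vs TT, aggressive vs controls
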