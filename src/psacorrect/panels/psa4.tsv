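rsid	effect_allele	other_allele	effect_size	genetic_model	locus_label	source
rs2736098	T	C	1.105	additive	TERT 5p15.33	per-allele +10.5% PSA, Icelandic GWAS discovery
rs10788160	A	G	1.102	additive	FGFR2 10q26.12	per-allele +10.2% PSA, Icelandic GWAS discovery
rs11067228	A	G	1.083	additive	TBX3 12q24.21	per-allele +8.3% PSA, Icelandic GWAS discovery
rs17632542	T	C	1.391	additive_shifted	KLK3 19q13.33	per-allele +39.1% PSA, Icelandic GWAS discovery; zero-dosage class absent in screened data
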