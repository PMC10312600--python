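site_id	gene	transcript_pos	contig	genomic_start	strand	codon_index	codon_offset	ref_codon	phasing
syn_43	Syn	43	syn_synth	42	+	15	1	AAT	independent
syn_55	Syn	55	syn_synth	54	+	19	1	AGA	independent
syn_58	Syn	58	syn_synth	57	+	20	1	AGA	independent
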