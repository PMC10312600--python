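site_id	gene	transcript_pos	contig	genomic_start	strand	codon_index	codon_offset	ref_codon	phasing
syx1a_730	Syx1A	730	syx1a_synth	729	+	244	1	ATG	independent
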