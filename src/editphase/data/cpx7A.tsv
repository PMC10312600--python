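site_id	gene	transcript_pos	contig	genomic_start	strand	codon_index	codon_offset	ref_codon	phasing
cpx_375	cpx	375	cpx7A_synth	374	+	125	3	ATA	phased
cpx_388	cpx	388	cpx7A_synth	387	+	130	1	AAT	phased
cpx_389	cpx	389	cpx7A_synth	388	+	130	2	AAT	phased
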