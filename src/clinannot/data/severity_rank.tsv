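term_name
transcript_ablation
splice_acceptor_variant
splice_donor_variant
stop_gained
frameshift_variant
stop_lost
start_lost
trinucleotide_repeat_expansion
short_tandem_repeat_expansion
deletion
insertion
duplication
indel
inframe_insertion
inframe_deletion
missense_variant
splice_region_variant
synonymous_variant
5_prime_UTR_variant
3_prime_UTR_variant
non_coding_transcript_exon_variant
intron_variant
upstream_gene_variant
downstream_gene_variant
intergenic_variant
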