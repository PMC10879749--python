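term_name	accession
transcript_ablation	SO:0001893
splice_acceptor_variant	SO:0001574
splice_donor_variant	SO:0001575
stop_gained	SO:0001587
frameshift_variant	SO:0001589
stop_lost	SO:0001578
start_lost	SO:0002012
trinucleotide_repeat_expansion	SO:0002165
short_tandem_repeat_expansion	SO:0002162
deletion	SO:0000159
insertion	SO:0000667
duplication	SO:1000035
indel	SO:1000032
inframe_insertion	SO:0001821
inframe_deletion	SO:0001822
missense_variant	SO:0001583
splice_region_variant	SO:0001630
synonymous_variant	SO:0001819
5_prime_UTR_variant	SO:0001623
3_prime_UTR_variant	SO:0001624
non_coding_transcript_exon_variant	SO:0001792
intron_variant	SO:0001627
upstream_gene_variant	SO:0001631
downstream_gene_variant	SO:0001632
intergenic_variant	SO:0001628
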