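term_a	term_b
trinucleotide_repeat_expansion	repeat_expansion
short_tandem_repeat_expansion	repeat_expansion
trinucleotide_repeat_expansion	short_tandem_repeat_expansion
inframe_deletion	deletion
inframe_insertion	insertion
indel	delins
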