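n_exons = 3
exon_lengths = 12,12,12
isoform_patterns = 110,111
substitution_rate = 0.0
signature_per_exon = true
disorder_exons = 3
seed = 1
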