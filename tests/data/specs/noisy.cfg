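# As three_patterns but with 15% per-residue substitution noise in species B.
n_exons = 4
exon_lengths = 15,12,18,10
isoform_patterns = 1100,1110,1011
substitution_rate = 0.15
signature_per_exon = true
disorder_exons = 3
seed = 11
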