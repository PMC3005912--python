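group_id	isoform_id	gene_id	species
G1	G1_A1	geneA	speciesA
G1	G1_A2	geneA	speciesA
G1	G1_B1	geneB	speciesB
G1	G1_B2	geneB	speciesB
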