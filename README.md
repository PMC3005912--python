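# isortho — transcript-level refinement of orthologue groups

Orthologue databases pair genes across species one-to-one, but most
multi-exon genes make several splice isoforms, and isoforms of the
*same* gene can differ in domain content, disorder, and function.
Annotating "the gene" therefore transfers function across species at
the wrong granularity. `isortho` refines a two-species one-to-one
orthologue group into **transcript-level sub-clusters**: sets of
isoforms, across species, that share the same exon structure and can
safely share annotation. It is a library plus a small CLI aimed at
comparative genomicists and annotation pipelines.

## Method

For all isoforms of a group, globally multiply aligned, the similarity
of a pair (P1, P2) is computed on the pair's projection of the MSA
(columns gapped in both rows removed):

    Sim(P1, P2) = (# identity-or-substitution columns) / (total aligned length incl. gaps)

with 0 ≤ Sim ≤ 1, after dropping maximal residue–residue runs shorter
than d = 2 columns from the numerator (an MSA-noise guard). Exons
skipped in one isoform appear as gap blocks and lower the score, so
Sim reflects shared exon structure — e.g. with three equal-length
exons, a two-exon isoform scores 2/3 against a three-exon partner and
1 against its matched-structure orthologue.

Sub-clusters are then built by a seed-and-expand iteration: the
best-scoring cross-species pair anchors a cluster, same-species
isoforms scoring *strictly above* the anchor-pair score join it, and
the process repeats on the remainder, leftovers becoming singletons.

Sub-clusters can be verified against two independent measures:
`diff_func`, the Hamming distance between binary
functional-signature presence vectors (built over the group-wide
signature universe from InterProScan-style output), and `diff_dis`,
the absolute difference in predicted intrinsic-disorder region counts
(regions < 10 aa ignored, regions separated by < 3 aa merged).
Per-group intra- vs inter-cluster averages of each measure are
compared with a Wilcoxon rank-sum test (exact for small samples,
tie-corrected normal approximation otherwise).

## Worked example

Simulate the canonical toy group — two species, two isoforms each,
one isoform per species skipping the third of three equal-length
exons — then cluster and verify it:

```bash
isortho simulate --spec tests/data/specs/fig1.cfg --out-dir demo/data
isortho cluster --fasta demo/data/isoforms.fasta --manifest demo/data/manifest.tsv \
    --out-clusters demo/clusters.tsv --out-similarity demo/sim.tsv
isortho verify-func --clusters demo/clusters.tsv --interpro demo/data/signatures.tsv \
    --out-summary demo/func.tsv --out-stats demo/func.json
```

`demo/sim.tsv` holds the six pairwise scores:

```
group_id  id1     id2     sim
G1        G1_A1   G1_A2   0.666667
G1        G1_A1   G1_B1   1.000000
G1        G1_A1   G1_B2   0.666667
G1        G1_A2   G1_B1   0.666667
G1        G1_A2   G1_B2   1.000000
G1        G1_B1   G1_B2   0.666667
```

The matched-structure cross-species pairs (A1–B1, A2–B2) score exactly
1; every mixed pair scores 2/3 because the extra exon is matched by a
gap block spanning one third of the projection. Clustering
(`demo/clusters.tsv`) turns the single gene-level orthologue pair into
two transcript-level sub-clusters, neither expanded since the
in-species scores (2/3) do not exceed the anchor score (1):

```
group_id  cluster_index  isoform_id  species   is_anchor  anchor_score
G1        1              G1_A1       speciesA  true       1.000000
G1        1              G1_B1       speciesB  true       1.000000
G1        2              G1_A2       speciesA  true       1.000000
G1        2              G1_B2       speciesB  true       1.000000
```

The functional summary (`demo/func.tsv`) confirms the split: with
per-exon signatures, isoforms in the same sub-cluster have identical
signature vectors and isoforms in different sub-clusters differ by the
skipped exon's signature:

```
group_id  measure  intra_mean  inter_mean  n_intra_pairs  n_inter_pairs  excluded
G1        func     0.000000    1.000000    2              4              false
```

The same works on real data: point `--fasta`/`--manifest` at your
sequences and group table, optionally `--alignments` at a directory of
precomputed per-group MSAs (e.g. MUSCLE output), and feed genuine
InterProScan TSV / disorder-predictor tracks to the verify commands.

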