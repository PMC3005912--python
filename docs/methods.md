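# Methods

## Problem and model

Orthologue databases relate genes one-to-one across species, but a
multi-exon gene typically encodes several splice isoforms, and function
annotated on one isoform need not transfer to another. `isortho`
refines a one-to-one two-species orthologue group into transcript-level
sub-clusters so that annotation transfer can be restricted to isoforms
with the same exon structure.

The central quantity is a global, alignment-projected similarity. All
isoforms of a group are multiply aligned; for a pair (P1, P2) the MSA is
projected onto the two rows, columns gapped in *both* rows are removed,
and

    Sim(P1, P2) = (# columns where both rows carry a residue) / (projection length)

so 0 ≤ Sim ≤ 1. Identities and substitutions count alike: a
residue–residue column is evidence the isoforms share that exon,
whatever the residues are, so no substitution matrix enters the score
(the substitution matrix is used only to *build* the alignment).
Skipped exons become gap blocks in one row and drag the score down —
which is the point: a local aligner would score two isoforms sharing a
subset of exons as a perfect hit.

Two modelling choices deserve emphasis:

* **Double-gap columns are excluded from the denominator.** In a
  four-isoform group where two isoforms carry an extra exon, the exon's
  columns are gapped in both rows of the two-exon pair. Keeping them
  would cap that pair's score below 1; excluding them makes two
  isoforms with identical exon structure score exactly 1, which is the
  identity the sub-clustering relies on.
* **The d-filter.** Heuristic multiple aligners can pair a few stray
  columns inside what is really a gap block. Maximal residue–residue
  runs ("common regions") shorter than `d` residues (default d = 2) are
  therefore dropped from the numerator. The common regions are
  interpreted *pairwise* — runs in the two-row projection — so that
  Sim remains a function of the pair alone rather than of the whole
  group. By default the filtered columns stay in the denominator
  (`d_filter_mode = "numerator"`); removing them from both is available
  as `d_filter_mode = "both"`.

## Sub-clustering

Given the pairwise score matrix, the group is partitioned by a
seed-and-expand iteration: (1) the best-scoring cross-species pair
among unassigned isoforms becomes the *anchor pair* of a new
sub-cluster; (2) an unassigned same-species isoform joins if its score
to its species' anchor **strictly exceeds** the anchor-pair score;
(3) repeat while both species have unassigned isoforms; (4) leftovers
become singletons. Strictness matters: an isoform exactly tied with
the anchor score stays out (a `expand_on_tie` switch gives ≥ for
sensitivity analysis). Expansion is a single pass — membership depends
only on similarity to the anchor, never on other members — so
insertion order is irrelevant. Two determinism rules are fixed where
the procedure is otherwise underdetermined: tied anchor pairs are
broken on the lexicographically smallest sorted id pair, and singleton
clusters are emitted last in id order. Anchored clusters come out with
non-increasing anchor scores, since any pair available at a later
iteration was already available earlier.

## Alignment

The group MSA may be supplied precomputed (aligned FASTA, e.g. MUSCLE
output, validated against the group's sequences) or built by the
package's progressive aligner:

* pairwise global Needleman–Wunsch with affine gaps (Gotoh), BLOSUM62,
  gap open −10 (first gap column) and extend −1 — conventional protein
  defaults; the score's downstream use is structural (where the gaps
  fall), not quantitative;
* a UPGMA guide tree on pairwise distance 1 − fraction identity
  (UPGMA rather than NJ: within-gene isoform families are shallow and
  nearly ultrametric);
* leaf-to-root profile–profile merging, where a column-pair score is
  the mean residue-pair BLOSUM62 score over all sequence pairs, with
  gap symbols inside existing columns contributing 0;
* traceback ties resolved in the fixed order diagonal > up > left, so
  alignments are identical across runs and platforms;
* all-gap columns removed, row order following the input.

Ambiguity codes B/Z/X are scored by the matrix; U (absent from
BLOSUM62) scores 0. The pairwise aligner is verified against
exhaustive enumeration of all global alignments for short sequences,
using the same explicit gap-cost function for both routes.

## Verification measures

**Functional (diff_func).** Per group, the signature universe is the
sorted union of functional-signature accessions (InterProScan-style
assignments) hitting any group isoform; each isoform gets a binary
presence vector over that universe and diff_func is the Hamming
distance between vectors. Vectors are group-relative, so diff_func is
only defined within a group.

**Disorder (diff_dis).** Per-residue disorder scores are thresholded
at ≥ 0.5 (the predictors' documented default convention) into maximal
runs; regions separated by fewer than 3 ordered residues (i.e. 0–2
residues between them) are combined, and regions shorter than 10
residues are ignored. diff_dis is the absolute difference in region
counts. The order of the two cleaning rules is not canonical; merging
*before* the length filter is the default because two nearby
sub-threshold fragments plausibly represent one region, and the
opposite order is available via `disorder_order`. The cleaning is
idempotent, and the intervals dialect cannot express "no disordered
regions", so an isoform absent from an intervals file is treated as
fully ordered (with a warning).

**Summaries and test.** For each group, the pairwise difference is
averaged over pairs sharing a sub-cluster (intra — including
cross-species pairs, since "within a sub-cluster" carries no species
qualifier) and over pairs in different sub-clusters (inter). A side
with no pairs is reported as undefined, never as 0, and a group is
dropped from a side's distribution only where that side is undefined.
Groups in which every pairwise difference is 0 can be flagged excluded
(`skip_if_all_equal`, on by default in the CLI), matching the practice
of analysing only groups where differences exist. The per-group intra
and inter means then form two samples compared by the Wilcoxon
rank-sum (Mann–Whitney U) test. For n1 + n2 ≤ 12 the permutation null
of U is enumerated exactly, with midranks, which remains well defined
under ties (this is why identical samples give p = 1 in exact mode);
larger samples use the normal approximation with tie-corrected
variance and continuity correction. Two-sided p is reported by
default, with the one-sided "inter > intra" p alongside; p-values are
never floored to a display threshold.

## Synthetic data

`SynthSpec`/`generate_group` emulate the exon-skipping model of
isoform divergence: species A's gene is a list of distinct uniform
random amino-acid exon strings, species B's gene is a per-residue
substituted copy, and each isoform concatenates the exons of its
pattern bitmask, mirrored across species. Defaults are the canonical
worked example — three equal-length exons (12 aa, a deliberately small
but alignable exon size), patterns 110 and 111, substitution rate 0 —
under which the score matrix is exactly {1 for matched patterns, 2/3
for mixed pairs} and clustering recovers the two pattern classes.
Optional per-exon signatures (signature k present iff exon k is
included) and per-exon disorder intervals give verification measures
with zero intra-cluster difference by construction. Exon strings are
drawn with pairwise distinctness enforced so cross-exon alignments
cannot match by accident; no indels are introduced inside exons by
default (exon presence/absence is the model of isoform difference),
though an `indel_rate` exists for robustness experiments.

Recovery is scored against the true pattern partition with an
adjusted-Rand-style index: exactly 1.0 iff the partitions coincide,
clamped to [0, 1], with a pair-counting fallback for the degenerate
single-class and all-singleton truths where ARI is undefined.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: real exon length distributions and
sequence composition; splice variants other than whole-exon skipping
(truncated exons, alternate splice sites, mutually exclusive exons
appear only as their whole-exon approximations); paralogous
contamination of groups; annotation noise in signature assignments;
and correlated disorder predictions. Note also that because
substitutions still produce residue–residue columns, the similarity
score is by design almost invariant to substitution noise as long as
the alignment is correct; the noise sweep therefore probes alignment
robustness, not score robustness.

## Problem sizes and numerical choices

The test suite runs the clustering oracle comparison on 500 random
groups of ≤ 8 isoforms with tie-rich score grids, the alignment oracle
on sequences of ≤ 6 residues over a 3-letter alphabet (small alphabets
make score ties, the hard case, common), exact-vs-enumeration rank-sum
checks up to n1 + n2 = 10, noise-free parameter recovery over 50
seeded specs, and a noise sweep of 100 replicates at each substitution
rate in {0, 0.05, 0.15, 0.3} — sizes chosen so the whole suite runs in
well under a minute while exercising every tie-break path.
Floating-point score comparisons in the aligner's traceback use an
absolute tolerance of 1e-9 against accumulated sums; similarity values
are exact rational arithmetic in floating point (counts divided by
counts) and are compared exactly where the model predicts exact values.

## Known limitations

* The anchor iteration is greedy; a group whose best cross-species
  pair is an artefact of alignment error can seed a wrong cluster, and
  nothing revisits earlier clusters.
* diff_func inherits the domain-level granularity of signature
  databases: isoforms differing inside one domain are invisible to it.
* diff_dis compares region *counts* only — two isoforms with equal
  counts but very different disorder content score 0 (the disorder
  fraction is computed and reported but deliberately not used in the
  difference measure).
* The built-in progressive aligner is adequate for within-gene isoform
  families (near-identical over shared exons); it is not a general
  MSA tool, and genuinely diverged sequences should be aligned
  externally and ingested.
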