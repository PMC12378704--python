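# Methods

## Scope and model

`imprior` prioritizes candidate i-motif (iM) loci by combining three
signals: (1) presence of the C-rich structural grammar (C₃N₁₋₁₂)₃C₃,
(2) positional conservation across all genomic instances of that grammar,
captured by an alignment-derived position-specific similarity matrix
(PSSM), and (3) statistical separation of each instance's PSSM score
from a within-sequence shuffle null. The premise is that motifs that are
positionally conserved across many loci are more likely to be
structurally and functionally relevant than random C-rich sequence.

## Scanning

Matching uses standard regex semantics: non-overlapping, leftmost,
greedy. This is a real modeling choice — adjacent C-runs closer than 13 nt
can chain into a single long match, and overlapping or nested instances
are not enumerated — so total match counts are only comparable between
runs using the same semantics. Coordinates are 0-based half-open
(BED convention) everywhere internally; reverse-strand hits are found on
the reverse complement and mapped back via start_ref = L − end_rc.
Matches can never span an N because the loop class is restricted to
A/C/G/T; any other character in the input is rejected at load.

## Alignment

Groups are (chromosome × strand), each match extended by up to 3 nt of
flanking reference sequence in motif orientation (truncated at contig
ends). The builtin engine is a classical progressive aligner: UPGMA
guide tree on 1 − Jaccard(3-mer) distances (scipy average linkage),
profile–profile Needleman–Wunsch with match +1, mismatch −1, linear gap
−2, column scores averaged over residue pairs, and a fixed
diagonal > up > left traceback tie-break. Given input order (genomic
coordinate order) the result is deterministic. The engine is pluggable:
`external` shells out to `mafft` over FASTA streams; any aligner that
round-trips FASTA could be substituted. No attempt is made to reproduce
any specific external tool's scoring model — conservation statistics,
not a particular alignment, are the goal.

## PSSM and scoring

Column frequencies exclude gaps; scores are
log₂((count_b + ε) / (n_nongap + 4ε) / 0.25) with pseudocount ε = 0.25
per base (configurable). The log base only rescales scores and therefore
ranks; the pseudocount only matters for depleted bases, whose negative
scores are truncated to zero by the positive-sum rule anyway. A
sequence's score sums strictly positive column scores along its row;
gaps contribute zero (no gap penalties), so the score is monotone in
agreement with the consensus and never negative. For sequences that were
never part of the alignment (e.g. G-quadruplex controls), the sliding
score takes the maximum positive-sum over every integer offset against
the matrix, with overhanging positions contributing zero: the maximum is
the only aggregation that yields a single score comparable with aligned
scores.

## Permutation significance

The null for a row is generated by uniformly shuffling its own
nucleotides and re-inserting them into the row's non-gap columns, keeping
the gap structure fixed; B = 1000 shuffles are scored (vectorized over
permutations). Two tail probabilities are reported:

* **t-based p** (the significance filter): t = (S − μ)/(σ/√B), B−1 df,
  upper tail. Dividing by σ/√B treats the null mean as the estimated
  quantity, which makes the filter extremely permissive — nearly every
  genuine motif instance passes, and the subsequent Z-ranked top-5% cut
  does the real work. This is intentional: the filter removes only
  sequences indistinguishable from their own shuffle.
* **empirical p** = (1 + #{null ≥ S})/(B + 1): the calibrated permutation
  tail probability at resolution 1/B. This is the quantity that behaves
  like a p-value under the null (verified by the calibration tests); the
  t-based p is deliberately anti-conservative and should not be
  interpreted as a frequency.

Degenerate nulls (σ = 0, e.g. homopolymer rows, detected at relative
tolerance 1e−9) give z = 0 and p = 1 unless the observed score exceeds
the null mean, in which case p = 1/(B+1). BH adjustment is applied to
the t-based p across all groups jointly; selection keeps
⌊0.05 × N_total⌋ candidates by Z among those with q < 0.05, with ties
broken by score then genomic coordinate. N_total is the total scanned
match count, so the q filter can only shrink the selection. Each row
draws an independent child seed from the pipeline seed, so results are
reproducible and independent of group iteration order.

## Annotation

Gene-body overlap and nearest-gene lookup run through pyranges; the gap
distance is recomputed arithmetically (pyranges reports adjacent
intervals as distance 1). The promoter is TSS − 2000 / + 200 nt,
strand-aware and configurable — "promoter" has no universal definition,
so region percentages shift with this window. Region precedence is fixed
as promoter > 5′UTR > 3′UTR > exon > intron > distal intergenic; a
candidate gets exactly one region. Gene-class enrichment builds the 2×2
table (immune vs housekeeping) × (hit by candidate vs background only)
and uses the conditional Fisher exact test (scipy), with the
conditional-MLE odds ratio and test-inversion CI. Immune and
housekeeping lists are user-supplied one-symbol-per-line files.

## Validation

Levenshtein distance is computed with edlib; Jaccard similarity over
distinct 3-mers. A candidate is labeled iM-like when strictly more
similar to the positive than to the negative control set; an exact tie
classifies negative (conservative — with real control sets ties
essentially never occur). The ROC cutoff is Youden's J on the
max-similarity-to-positives score; with completely separated groups any
threshold in the gap is optimal and the reported cutoff is the smallest
positive-group similarity that sklearn's ROC grid visits. The rank-sum
test uses the Mann–Whitney U of the first sample, exact enumeration for
n+m ≤ 10 without ties, otherwise the normal approximation with tie and
continuity correction.

The random forest (scikit-learn, 500 trees) sees five features per
sequence: A/C/G/T proportions and length. mtry (`max_features`) is tuned
over {1..5} by 10-fold stratified CV accuracy on a stratified 70%
training split; all reported metrics come from the held-out 30%. The
classifier is a validation instrument, not a deliverable model.

## Synthetic fixtures

The generator implants grammar-sampled motifs into backgrounds with no
CCC and no GGG substring (per-position sampling with a two-base memory),
so neither strand contains spurious matches. To make the
scanner-recovers-truth round trip exact under greedy matching, implant
loops avoid C/G at their edges and CC/GG internally, and the single
background base flanking each implant is forced to A or T; half the
implants are inserted as reverse complements and recorded on the minus
strand. A toy gene track places an "immune"-labeled gene around a
configurable fraction of implants, terminal exons at gene edges (so
implants are intronic), and "housekeeping" genes in reserved
implant-free segments. The fixtures reproduce the combinatorial
structure the pipeline exploits — they do not emulate real base
composition, repeat content, or chromatin context, so passing tests
demonstrate correctness of the machinery, not biological performance on
a real genome.

Default study conditions used by the tests and the acceptance script:
B = 1000 permutations (reduced to 200–300 on the larger fixtures to keep
runs short; the z and q values saturate well before that), q < 0.05,
top 5%, flank 3, k = 3, 70/30 split, 10 folds, 500 trees; fixture sizes
of 50 implants (recovery), 1,000 implants (selection), 285 + 285
(control comparison, matching the published control-set sizes) and
1,285 positives vs 285 + 1,000 negatives (balanced classifier set).

## Known limitations

* Non-overlapping greedy matching undercounts nested/overlapping
  instances by construction; no alternative enumeration is provided.
* The builtin aligner is O(n²) in group size for the guide tree and is
  intended for fixtures and moderate groups; genome-scale runs should
  use the external engine.
* The t-based p-value is a filter, not a calibrated error rate; use the
  empirical permutation p for inference.
* Region percentages depend on the promoter window and precedence
  definitions above and are not exactly comparable across tools that
  define them differently.
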