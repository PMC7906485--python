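# Methods

## Model and procedure

The package treats biclustering as exhaustive combinatorial search over
feature subsets. A loading matrix L (n subjects × m features) is first
decomposed feature-by-feature into *sorted components* (SCOMPs): for each
feature, the subset of subjects whose loading is extreme under one of four
rules. A bicluster is then a feature subset (|F| ≥ K) whose SCOMP
intersection retains at least N subjects; by construction its submatrix is
homogeneously high-loading, which is the coherence notion the method
targets. Because set intersection is commutative, the *candidate* set is
identical for every ordering of the features; orderings matter only through
the depth-first discovery order, which determines which of two overlapping
candidates is kept by the local validator. Repeating the search over many
orderings and counting rediscoveries (the *frequency*) therefore measures
how robust each bicluster is to that arbitrary tie-breaking — the method's
stability criterion.

Key choices a user controls:

| parameter | meaning | default | notes |
|---|---|---|---|
| N | minimum subjects per bicluster | 1 (CLI demos: 11 / 35) | count |
| K | minimum features per bicluster | 2 | count; K ≥ 2 |
| O | allowed overlap percent | 35 | fTH1 = O/100 |
| OE | cross-permutation overlap percent | = O | fTH2 = OE/100 |
| M | sorting rule | 4 | 1 signed submeans, 2 signed quartiles, 3 absolute value, 4 positive-or-negative |
| permutation_budget | orderings evaluated | 720 | all m! when m! ≤ budget, else seeded uniform sample, identity first |
| min_frequency | stability cutoff | 2 | a bicluster seen under a single ordering is not considered stable |

The two F1 thresholds are the minimum values implied by the size gates
(overlap fraction O/100 of the smallest admissible bicluster); "too
similar" is read as F1 ≥ threshold, so O = 100 blocks only exact
duplicates.

### Sorting-rule details and numerical choices

Zero loadings belong to neither the positive nor the negative subsample in
rules 1–2 (signs are read strictly). Rule 2 uses linear-interpolation
percentiles over each signed subsample with closed boundaries. Rule 4 keeps
the boundary subject on the positive branch (x ≥ mean) and drops it on the
negative branch (x < mean). All closed comparisons carry a 1e-12 absolute
tolerance so that a constant column is not split by round-off in its own
mean; an all-zero column selects every subject under rules 3–4 (|mean| = 0)
and none under rules 1–2 (empty signed subsamples).

### Search mechanics

Subsets are enumerated by depth-first prefix extension in the ordering's
sequence; every subset of size ≥ K appears exactly once. The running SCOMP
intersection is carried down the recursion and branches are pruned as soon
as it drops below N — exact, because intersections are monotone
nonincreasing in the feature set. Intersections are memoized across
orderings (they depend only on the subset), so additional permutations cost
only validation work. Within an ordering, the local validator is
first-come-first-kept; across orderings, a rediscovery (max F1 ≥ fTH2)
increments the frequency of the *earliest* best-matching incumbent and
keeps the incumbent's membership unchanged (a union-merge could break the
exact-intersection invariant). Everything is deterministic given the seed;
permutation sampling is uniform without replacement with the identity
ordering always first.

### Association stage

A bicluster's composite expression is the subject-wise mean loading over
its imaging features. By default, Pearson correlation with each symptom
score is computed across the bicluster's own subjects (`subjects="all"`
switches to the whole cohort, a second legitimate reading when subgroup
membership itself carries the signal). P-values are BH-adjusted within each
symptom's family by default (`fdr_family="global"` pools all pairs).
Pairs with fewer than 3 usable subjects or zero variance are flagged
not-computable rather than reported as NaN. Significance requires
|r| ≥ 0.4 and adjusted p ≤ 0.05 for at least one score.

## Synthetic data: what it emulates and what it does not

`generate_base_matrix` draws each feature column from a normal distribution
with its own mean (uniform in ±0.3) and SD 0.3, clipped to [−1, 1] — an
idealization of ICA loading columns, which are roughly unimodal,
mean-offset and bounded. Clipping (rather than rejection sampling) slightly
inflates mass at ±1; at these parameters the effect is negligible.

`embed_biclusters` plants blocks by re-drawing planted cells uniformly from
[0.8, 1.0] and then enforcing that every planted cell sits at least 0.05
above the column's post-embedding positive mean (the threshold of sorting
rule 1, and an upper bound on rule 3's and rule 4's thresholds whenever the
column mean is nonnegative). Raising cells raises the positive mean, so the
enforcement iterates; the floor is monotone increasing and either
stabilizes or exhausts the headroom below 1. No strict-margin fixed point
exists when planted cells dominate a column's positive entries (a set's
minimum cannot exceed its own mean); such columns fall back to a single
common planted value at or above the background positive mean, which
satisfies the closed (≥) selection inequalities exactly. Consequence worth
knowing: in the 400-subject design a planted column with a strongly
negative base mean can keep a negative overall mean, and sorting rule 4
then selects *below*-mean subjects, excluding that block — a real
interaction between the generator's mean range and rule 4, not an artifact
of the implementation.

`generate_symptom_coupled` appends questionnaire-style columns: a weighted
sum of the standardized block-membership indicator (weight = coupling) and
unit Gaussian noise, mapped to mean 28 / SD 7 and clipped to the PANSS-like
range [7, 49]. Membership coupling is constant within a block, so
within-bicluster correlations are blind to it; the all-subject reading is
the one with power against this generator.

What passing tests on these fixtures do **not** show: robustness to
heavy-tailed or skewed loading distributions, site/batch structure,
missing symptom data, correlated features, or subgroups that express
*weakly* rather than strongly on a component. Real-data behaviour on
multi-site cohorts is out of reach of these simulations.

## Problem sizes used in the shipped checks

The recovery check runs the 40 × 10 design over 200 permutations × 20
seeds; the sorting-rule comparison runs the 400 × 10 design over 100
permutations per rule × 10 seeds; the null-association control runs 100
seeded cohorts. These sizes were chosen once as representative of the two
designs while keeping the whole suite in tens of seconds.

## Known limitations

- Full m! enumeration is infeasible beyond m ≈ 8; the permutation budget
  caps the orderings evaluated. Because candidates are order-invariant,
  extra orderings only refine the stability frequencies and validation
  tie-breaks, but reported frequencies are relative to the budget, not m!.
- The incumbent-keeps-membership merge rule means that in noisy regimes the
  first orderings' acceptances anchor the final memberships; with dense
  SCOMPs (rule 3 or 4 on large cohorts) this caps best-match recovery of
  planted blocks even when the blocks are rediscovered in every ordering.
  The per-block F1 columns of `compare_sorting_methods` make this visible.
- The consensus score normalizes by the larger set's cardinality, so
  methods that extract many stable biclusters are penalized independent of
  recovery quality; read it alongside the per-block F1 values.
- No significance test for the existence of a bicluster is provided (no
  null model for the search itself); the association stage controls FDR
  only for the correlation screen.
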