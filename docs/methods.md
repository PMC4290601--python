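# Methods

## Data model and normalization

The unit of analysis is a features × samples numeric matrix with exactly two
class labels (e.g. `cancer` / `normal`), read from delimited text with the
labels in a separate two-column file. Raw intensity matrices are prepared by
quantile normalization (every column receives the common per-rank means)
followed by log2. Two conventions are worth stating because upstream
pipelines differ:

- **Ties in quantile normalization.** Tied values within a column receive the
  mean of the reference values at the ranks they jointly occupy (the
  "average" dialect used by most array pipelines). Consequences: with ties
  present, column multisets agree only up to the tie-averaging, and a second
  application is no longer an exact fixed point. For tie-free (continuous)
  data, quantile normalization is exactly idempotent and all column
  multisets coincide; the test suite checks both the exact tie-free
  properties and the tie rule itself.
- **Pseudocount.** `log2_transform` defaults to pseudocount 0 and rejects
  non-positive values by naming the offending cell; array intensity data is
  positive, so a silent offset would only hide upstream problems.

## Gain ratio and trees

For a continuous feature, candidate thresholds are the midpoints of
consecutive distinct sorted values; the score is

    GR = max_t  [ H(y) − (n_L H(y_L) + n_R H(y_R)) / n ] / H(n_L/n)

with entropies in bits and the denominator the entropy of the partition
*sizes*. Thresholds with non-positive information gain are ignored; a
constant feature scores 0. The score is invariant to strictly monotone
per-feature transforms and bounded by 1.

Tree induction uses the same scan with two C4.5-style refinements that are
deliberately **not** applied at the single-feature ranking stage (ranking a
single attribute has no multi-way split-info bias to correct):

- per feature, only thresholds whose raw gain reaches the mean gain of that
  feature's positive-gain candidates compete (`gain_mean_filter`, default
  on);
- both children must hold at least `min_leaf` samples (default 2).

Recursion stops at pure nodes, nodes smaller than `2·min_leaf`, or when no
candidate split remains. `≤` routes left, `>` routes right, everywhere;
leaves take the majority label, ties resolved by the larger class prior in
the full training set, then lexicographically. A `data_value` threshold
style (threshold at the lower of the two straddling values, the classic
dialect) is available because published trees from other implementations may
follow either convention.

One limitation is inherited from the split criterion: a concept whose every
axis split has zero information gain (exact two-feature XOR) cannot be
learned, because no first split is ever made. The test suite therefore
exercises the "both features required" property with a conjunctive concept
instead.

## Committee by iterative root removal

The first tree is induced on the candidate feature set; each subsequent tree
is induced after deleting the previous root feature, until two features
remain. With `k` candidates and a root split in every tree the committee has
exactly `k − 1` members; an unsplittable (single-leaf) tree stops the
iteration early with a warning. Rules are harvested from every
root-to-*pure*-leaf path (only pure leaves can possibly achieve zero
other-class coverage), merged per feature into closed intervals, restricted
to 2–3 distinct features, and always re-validated against the full matrix.
A path that tests one feature in both directions yields a two-sided
conjunct; this is allowed for committee rules and canonicalized.

## 100%-frequency rules and the exhaustive search

A rule is a conjunction of per-feature intervals, closed on finite sides,
with a target class; it is *valid* iff it covers every target-class sample
and no other-class sample of the training matrix. The exhaustive search
scans all feature subsets of arity 2 or 3, all orientation vectors in
`{≤, ≥}^arity`, and both classes. For a given orientation the tightest
covering bounds are the target-class extremes; validity is decided there
(any looser bound can only admit more of the other class, so this decision
is exact). Two bound-placement conventions are reported:

- `midpoint` (default): the finite bound moves halfway toward the nearest
  excluded other-class value beyond the extreme, falling back to the extreme
  when no such value exists. This matches the tree module's threshold
  dialect, so committee-harvested and exhaustively mined duplicates of the
  same rule carry identical bounds and merge cleanly.
- `extreme`: the bound stays at the target-class extreme (also the form a
  grid-enumeration oracle produces, which is how the search is tested).

The midpoint placement never changes validity: along each axis the midpoint
lies strictly below the nearest excluded value, so no other-class sample can
enter through the widened side.

**Minimality.** An arity-2 rule is dropped when one of its features
separates the classes alone; an arity-3 rule is dropped when any 2-feature
subset admits a valid rule for the same class (this also removes triples
containing a lone separating feature). Exact duplicates — same features,
same bounds, same class — collapse to a single entry with merged
provenance. The count of rules therefore depends on this convention;
alternative dedup choices (e.g. by feature set only) would give different
totals on the same data.

**Complexity.** The arity-3 scan is `O(F³ · 8 · n)` in the number of
features `F`; for wide matrices a `max_features` cap pre-ranks features by
gain ratio and searches the top slice only.

## Max-Min distance separation

Every rule's reliability score is the minimum Euclidean distance between
any cross-class sample pair, computed over **all** samples of both classes
restricted to the rule's 2–3 features, on the normalized expression values
with no per-feature rescaling by default (a `minmax` option exists because
printed distances in the literature cannot settle the convention). Rules are
ranked per arity stratum (distance descending, ties by feature ids) and the
top `⌈k/3⌉` of each stratum are selected. The ceiling-third formula is
implemented exactly as stated even though one published account selects
three of six 3D rules where `⌈6/3⌉ = 2`; the discrepancy is documented, not
resolved by guessing. Distances are monotone under adding features and
homogeneous under rescaling all values, both of which are property-tested.

## Validation machinery

- **Cross-validation**: stratified k-fold (scikit-learn's splitter, seeded),
  remainder samples distributed round-robin — with 10 controls and 5 folds
  this puts two controls in every test part. Metrics are pooled confusion
  counts (sensitivity, specificity, accuracy, F1 of the positive class —
  the disease class by default, configurable) plus the mean per-fold
  Mann–Whitney AUC with average-rank tie correction. Scores: Laplace-
  smoothed leaf fractions `(n⁺+1)/(n+2)` for the tree, nearest-neighbour
  distance ratio for 1-NN, Gaussian posteriors for naive Bayes.
- **Randomization test**: the null distribution of CV mean AUC over uniform
  random feature subsets of fixed arity; one fold layout (derived from the
  seed) is shared by all draws so the per-subset statistic is deterministic
  and the empirical exceedance table `P(AUC ≥ t)` is comparable to exact
  enumeration over subsets. Exceedance is non-increasing in the threshold by
  construction.
- **Label-permutation test**: the *entire* discovery pipeline (ranking →
  candidate selection → committee + exhaustive search → pooling) is re-run
  under uniform label shuffles and the surviving rule count recorded; on
  genuinely structured data the true labels yield rules and shuffled labels
  essentially never do.
- **Training-test protocol**: per fold, features are re-ranked and
  re-projected on the training part only, rules re-discovered, the Max-Min
  best rule applied to the held-out part as a classifier (inside the box →
  rule class, else the other class).

A caution about null baselines: cross-validated *accuracy* of a flexible
classifier on label-independent data is biased **below** the majority-class
rate (overfitting costs test accuracy), so the correct null expectations are
AUC ≈ 0.5 and accuracy not exceeding the majority rate — which is what the
tests assert.

## Synthetic data generator

The generator emulates the regime that motivates the method: a small,
imbalanced two-class cohort (defaults 10 vs 61 samples) on a post-log2
intensity scale (baseline 8.0, noise sd 0.5 — Gaussian, since the method
operates after log2). Null features are i.i.d. Gaussian for all samples.
Each planted 2-/3-feature group places the target class on one side of a
per-feature boundary (folded-normal noise toward the inside) and makes every
non-target sample violate exactly one axis (cycling over axes) by
`margin` plus folded noise, with the remaining coordinates drawn like the
target's. Consequences, by construction:

- the minimum inter-class distance in the planted subspace is at least
  `margin`;
- no single planted feature separates the classes (every axis has violators
  and non-violators), so the joint rule is required, as with real
  multi-marker signatures;
- the exhaustive search recovers the planted group, and with
  `margin/noise ≥ 5` the full pipeline ranks it first in its stratum in
  ≥ 95% of seeded runs (checked over 50 seeds).

What the generator does **not** emulate: array-specific artifacts
(background subtraction, faint-spot filtering, spatial effects), correlated
feature blocks, or class-dependent variance. Passing tests on this generator
therefore demonstrate the machinery's correctness and calibration, not
performance on any particular clinical dataset. Both classes hug their
boundaries (folded noise), so learned interval bounds sit essentially at the
training class extremes; held-out samples occasionally cross them, which is
why cross-validated accuracy of discovered rules is high but not 1.0 — the
same behaviour reported for this class of methods on real cohorts.

## Problem sizes and numerical choices

- Test-suite simulations use 6–10 controls vs 14–61 cases, 5–20 features,
  50 recovery seeds, 100 label permutations and 200 rule-validity datasets —
  sizes chosen to exercise the small-`n` pathologies (fold constraints,
  margins dominated by the small class) at desk scale.
- Gains below `1e-12` bits count as zero; rule-coverage comparisons are
  exact closed-interval float comparisons (no epsilon), since bounds are
  constructed from the data itself.
- Determinism: ranking ties break lexicographically; split ties by (feature
  id, threshold); rule orderings by (features, orientation); all stochastic
  procedures take explicit integer seeds and are reproducible bit-for-bit.
- The acceptance script reports the committee-length computation (19
  informative features, 10 vs 61 samples → 18 trees) because it is the one
  headline quantity that is a deterministic function of the method's
  structure rather than of a particular dataset.

## Known limitations

- 100%-frequency rules are training-set constructs; their bounds do not
  transfer across platforms, and the package deliberately provides no
  cross-dataset threshold transfer — only re-evaluation of the *features* on
  independent data.
- The exhaustive search is limited to arities 2 and 3 (4+ miRNA rules are
  out of scope) and one-sided conjuncts per interval end.
- Exact reproduction of values deposited in public series is not guaranteed
  when the upstream tie rule or C4.5 dialect differs; both threshold styles
  and both bound conventions are exposed for that reason.
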