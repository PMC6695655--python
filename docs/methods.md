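# Methods

This note documents the models, conventions and numerical choices behind
`srdeval`, in the spirit of a statistics package's methods appendix.

## Synthetic ordinal-toxicity datasets

The generator emulates descriptor tables for compounds binned into ordinal
GHS toxicity categories (1 = most benign). Its defaults define the study
conditions used throughout the tests.

**Feature model.** Every informative descriptor is an equally noisy proxy
of a latent toxicity axis: for class *c* it is drawn i.i.d. from
N((c−1)·s, 1), where *s* = `separation` is the inter-class mean shift in
within-class standard deviations. Class means advance monotonically along
the latent axis, so adjacent categories are the hardest to separate — the
difficulty structure of ordinal multiclass problems. With *d* informative
features the effective (Mahalanobis) separation between adjacent classes is
s·√d; `separation=0` yields pure noise (chance performance downstream) and
`separation=6` yields near-perfect separability even from a single
attribute.

**Pathological columns.** `n_duplicate_features` adds noisy copies of
informative columns with noise amplitude 0.045·sd, giving an expected
Pearson correlation of ≈ 1/√1.002 ≈ 0.999 — reliably above the 0.997
filtering threshold. `n_constant_features` adds columns with sd ≈ 10⁻⁴,
below the 0.001 threshold. Both exist to exercise the descriptor filter.

**Compositions.** Six presets reproduce the per-class train/test counts of
the three toxicity case studies (two 4-category aquatic-toxicity datasets,
one 6-category acute-oral dataset), each in a balanced and an imbalanced
training variant with identical test splits. One preset family
intentionally carries a balanced training count (28) that is *not* the
minimum of its imbalanced counts (48); the presets reproduce the published
compositions verbatim, while the `balance_classes` operation implements the
min-class downsampling rule. The two are deliberately not reconciled.

**Defaults.** `n_features=30`, `separation=0.3`, 3 duplicates, 2
near-constants. At 30 features, s = 0.3 puts adjacent classes ≈ 1.6
effective sd apart — hard enough that classifiers and metrics disagree
(the phenomenon under study), easy enough that all are far from chance.
Real descriptor tables differ in ways the generator does not model:
thousands of partially redundant, non-Gaussian, discrete and heavy-tailed
descriptors, label noise from assay variability, and train/test splits that
are not exchangeable draws. Passing tests therefore certify the *machinery*
(metrics, SRD, ANOVA, plumbing) and the qualitative behavior of the
classifiers, not quantitative performance claims on real toxicity data.

**Seeding.** One master seed per dataset spec; per-purpose child seeds are
derived with `numpy.random.SeedSequence`, so all outputs are reproducible
bit-for-bit.

## The 28-metric panel

Predicted labels are the per-row argmax of the class probabilities, ties
broken toward the lowest class code. The 2-class view takes the highest
ordinal class (most toxic) as "Actual +" by default.

Conventions for degenerate inputs:

- a zero denominator in a one-sided rate (e.g. no actual negatives) marks
  both members of the complementary pair NaN;
- LR+, LR− and DOR return **signed infinity** when only their denominator
  vanishes (a perfect classifier has DOR = +∞). Infinities rank at the
  extremes under fractional ranking, so they remain meaningful inside SRD;
  an optional +0.5 continuity correction is available and off by default;
- MCC and κ return 0 when their denominators vanish (no-information
  convention);
- EF uses the top ⌈x%·n⌉ samples (guaranteeing a non-empty top list), with
  tie groups straddling the cutoff contributing fractionally; ROC_EF is the
  linearly interpolated TPR at FPR = x% divided by x%. Default x = 5%.
- AUC is pair-counting with ties worth 1/2 (equivalently the rank-sum
  form); AUAC and AP are trapezoidal areas over the tie-grouped
  accumulation and precision–recall polylines (AP is the trapezoidal
  PPV–TPR area, not the step-interpolated variant); the average rank of
  actives uses fractional best-first ranks normalized by n.
- RIE sums exp(−α·rᵢ/n) over positive ranks, normalized by the expected sum
  for uniformly placed positives; BEDROC rescales RIE between its
  worst/best attainable values. Tied scores contribute their expectation
  over tie-breakings — each tie group's positives share the group's rank
  positions equally. (Plugging average ranks into the exponential would
  bias RIE: a perfect one-hot classifier would score BEDROC ≈ 0.06 instead
  of 1.) Default α = 20, the standard early-recognition weighting, since no
  canonical value is fixed for this panel; both α and x are configurable.

**Multiclass inputs.** ACC, BACC, MCC, κ use their closed multiclass forms
(which reduce exactly to the 2-class formulas at k = 2); the Brier score is
natively multiclass. Every other metric is evaluated k times with class j
as positive (scores = probability of class j) and averaged with the actual
class counts as weights; classes with no members get weight 0 and NaN class
values are skipped with weight renormalization.

## Classifier suite

Five members delegate to scikit-learn: Gaussian naive Bayes; 1-NN
(Euclidean); RBF-kernel SVM with Platt-scaled probabilities via internal
cross-validation and regularization left at implementation defaults
(deliberately non-optimized); bagging of 10 unpruned trees; random forest.
Six are implemented here:

- **HyperPipes** — per-class per-attribute min/max bounds; class score =
  fraction of attributes inside the class's bounds; probabilities by score
  normalization (uniform when all scores vanish).
- **OneR** — per attribute, sorted values are cut into buckets of ≥ 6
  values (never splitting ties; a short tail is absorbed into the last
  bucket); each bucket predicts its majority class; the attribute with the
  lowest training error wins. Probabilities are the selected bucket's class
  frequencies.
- **MultiBoostAB** — SAMME-reweighted boosting of depth-1 trees with
  wagging restarts: at each subcommittee boundary (⌈i·T/S⌉ for i < S,
  T = 10 iterations, S = 3 subcommittees) the sample weights are redrawn
  from Poisson(1). A stump that cannot beat chance ends its subcommittee.
  Prediction is the α-weighted vote, normalized.
- **Decorate** — candidate trees are trained on the real data plus
  artificial examples (per-attribute Gaussians with training mean/sd;
  zero-sd attributes stay constant) labelled inversely proportional to the
  current ensemble's probabilities; a candidate is kept only if ensemble
  training error does not increase; at most 10 accepted members within 30
  trials.
- **Ensemble Selection** — a library of probabilistic models (by default a
  varied mix of suite-style learners) is fitted on 75% of the training
  data; greedy forward selection **with replacement** picks up to 100
  additions minimizing hold-out RMSE against one-hot labels, stopping early
  if no addition improves (which makes the selection RMSE non-increasing);
  the selected bag is refit on the full training data and averaged.
  The 25% hold-out fraction is a package choice.
- **CFS-filtered classifier** — correlation-based feature subset selection:
  merit(S) = k·mean|r(f, y)| / √(k + k(k−1)·mean|r(f, f′)|), best-first
  search over single-feature additions, stopping after 5 consecutive
  non-improving expansions; an unpruned decision tree (the closest widely
  available analogue of the classic default) is fit on the subset. The
  merit formula and stopping rule are package decisions; the base learners
  for bagging, Decorate and the filtered classifier are unpruned trees.

All estimators emit probability rows summing to 1 (±1e-9) and accept
explicit seeds; the pipeline derives every seed from the master seed.

## SRD, CRRN and cross-validation

Ranks are fractional (average) for ties — this makes SRD symmetric in its
two arguments and is standard rank-statistics practice. ±∞ is permitted
(ranking at the extremes); NaN is rejected.

- **Reference fusion**: row-wise min / max / mean / median, or
  "oriented-best" (the hypothetical best method: row-wise max where the
  row's quantity is greater-is-better, min where smaller-is-better).
- **Normalization**: 100·SRD/SRD_max(m) with SRD_max(m) = m²/2 (even m),
  (m²−1)/2 (odd m); the closed form is verified against brute-force
  permutation maximization for m ≤ 8 in the test suite.
- **CRRN**: the null distribution of SRD between a random permutation and
  the reference ranking. Exact enumeration for m ≤ 9 (9! ≈ 3.6·10⁵
  permutations enumerate in seconds); seeded Monte Carlo (default 10⁵
  draws) beyond. The result carries the full distribution, the cumulative
  curve and the 5%/95% quantiles.
- **Cross-validation**: Monte-Carlo repartition — in each iteration the
  rows are randomly split into k folds and normalized SRD is recomputed on
  the complement of each fold (leave-one-fold-out, not resampling with
  replacement). Defaults: 5 folds × 10 iterations (50 samples per column)
  for the metric analysis, 7 folds × 1 for the classifier analysis. The
  headline SRD is always computed on all rows; the CV distributions are
  uncertainty diagnostics.

**COVAT** takes each column in turn as the reference and reorders the
resulting symmetric matrix by increasing row mean; heatmaps use an absolute
0–100 color scale. Cluster boundaries are not computed — grouping is left
to the reader or to an explicitly separate agglomerative step.

## Experiment pipeline

Per scenario (balanced/imbalanced × 2-class/multiclass) and dataset:
descriptor filtering (sd < 0.001, then greedy |r| > 0.997 in column order,
training-split statistics applied to both splits), extreme-class extraction
for 2-class scenarios (lowest + highest ordinal class, relabelled 1/2),
stratified 5-fold CV predictions pooled over folds plus an external-test
refit, panel evaluation, and assembly into a 22 × 28 evaluation matrix
(11 classifiers × {CV, test}).

**Metric analysis** (consensus reference): smaller-is-better columns are
negated; ±∞ entries are replaced by finite surrogates just beyond the
column's finite range (rank order — all SRD ever sees — is unchanged, but
the column norm and the row-mean consensus stay finite); each column is
scaled to unit Euclidean norm within its dataset block; blocks are stacked
(3 × 22 = 66 rows for the three-dataset design) and SRD is run against the
row-mean ("consensus") reference. Per-block unit scaling puts datasets on
an equal footing before stacking; the axis and scope of the normalization
are package choices.

**Classifier analysis** (hypothetical-best reference): the per-dataset
matrices are transposed (28 metric rows × 22 model columns) and SRD is run
against the oriented-best reference using each metric row's orientation —
per dataset, as the classifier comparison is reported per dataset. Model
building defaults to fivefold CV; a sevenfold option exists for both the
model-building and SRD stages since both conventions are in circulation.

**ANOVA**: the cross-validated normalized SRD samples form a long table
with factors F1 (composition), F2 (classification type) and F3 (metric, 28
levels, or classifier, 11 levels; the two validation modes of a classifier
pool into its F3 level). A fixed-effects full-interaction model is fit by
OLS with Type II sums of squares (Type I = Type II on a fully balanced
design); each of the seven terms gets an F statistic, p-value and a
significance flag at α = 0.05. Marginal means carry pooled-variance 95%
confidence intervals (residual variance pooled over the finest cells,
t-based half-widths). The full-interaction model refuses tables with empty
cells or single-replicate cells. SRD values enter untransformed.

## Numerical and testing choices

- Tolerances: exact identities (complement pairs, multiclass reductions,
  AUC oracle equivalence, SS decomposition) are asserted at 1e-12…1e-9;
  stochastic calibrations use pre-stated bands (type-I error 5% ± 1.5
  points at 1000 repetitions; recovery experiments ≥ 19/20 seeded runs).
- Test problem sizes are deliberately desk-scale (tens of compounds per
  class, ≤ 12 descriptors in pipeline tests) so the full suite runs in a
  few minutes; the statistical structure, not the size, is what the checks
  depend on.
- CSV is the single interchange format; undefined values are serialized as
  `+inf` / `-inf` / `NA` with a legend comment, and floats are written with
  `repr` so round-trips are exact.

## Known limitations

- The generator's Gaussian, identity-covariance feature model understates
  the redundancy and non-normality of real descriptor blocks; absolute
  metric values on real data will differ.
- The WEKA-era algorithms are faithful to their published descriptions,
  not bit-compatible with WEKA's outputs (tree induction details, tie
  handling and internal randomization differ).
- The CRRN null assumes a tie-free reference ranking; with heavily tied
  columns the null is slightly conservative.
- COVAT cluster boundaries and post-hoc multiple comparisons after ANOVA
  are out of scope.
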