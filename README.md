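# srdeval

Multi-level comparison of machine-learning classifiers **and** of the
performance metrics used to judge them, built around the **sum of ranking
differences (SRD)** statistic, with randomization-test validation, pairwise
SRD heatmaps (COVAT) and factorial ANOVA decomposition.

The package is aimed at cheminformatics / QSAR practitioners who face two
coupled model-selection questions: *which classifier is best for my
(often imbalanced, often multiclass) toxicity-category data*, and *which of
the many performance metrics should I trust when they disagree*. It
provides:

- a **28-metric performance panel** for probabilistic classifiers — the
  one-sided rates (TPR, FNR, TNR, FPR, PPV, FDR, NPV, FOR), the two-sided
  local metrics (ACC, BACC, F1, MCC, BM, MK, LR+, LR−, DOR, EF, ROC_EF,
  Cohen's κ, Jaccard, Brier score loss, RIE) and the global ranking metrics
  (AUC, AUAC, AP, BEDROC, average rank of actives), with multiclass
  generalizations (printed multiclass forms where they exist,
  count-weighted one-vs-rest averaging otherwise);
- an **11-algorithm classifier suite** as scikit-learn-style estimators,
  including faithful reimplementations of HyperPipes, OneR, MultiBoostAB,
  Decorate, Ensemble Selection and a CFS-filtered classifier;
- the **SRD machinery**: rank transforms with fractional ties, reference
  fusion (min/max/mean/median/hypothetical-best), normalization to 0–100%,
  the CRRN randomization test (exact enumeration for m ≤ 9, Monte Carlo
  beyond), leave-one-fold-out SRD cross-validation, and COVAT;
- **factorial ANOVA** of the cross-validated SRD values over the design
  factors (balanced/imbalanced × 2-class/multiclass × metric-or-classifier);
- a **synthetic data generator** that emulates ordinal GHS toxicity-category
  datasets (three case-study compositions, correlated and near-constant
  descriptor columns) so the whole pipeline is testable without downloads.

## The statistic

Given an evaluation matrix with objects in rows and methods in columns plus
a reference column (a benchmark or a row-wise data fusion), every column is
rank-transformed (fractional ranks for ties) and each method's SRD value is

SRD_j = Σ_i | r_i(column j) − r_i(reference) |,

the smaller the better. Values are normalized by the maximum
SRD_max(m) = m²/2 (even m) or (m²−1)/2 (odd m) and reported in percent. The
CRRN randomization test gives the null distribution of SRD for a random
permutation: methods inside the null's bulk are indistinguishable from
random ranking.

## Worked example

```python
import srdeval as sv

spec = sv.preset_compositions("dataset2-balanced", seed=0, n_features=12)
data = sv.filter_descriptors(sv.generate_dataset(spec))
preds = sv.run_scenario(data, ("NaiB", "lBk", "Hip", "RF"), cv_folds=5, seed=0)
matrix = sv.assemble_matrix(preds)
print(matrix[["ACC", "BACC", "MCC", "AUC", "B"]].round(3))
```

```
         ACC   BACC    MCC    AUC      B
NaiB   0.491  0.491  0.323  0.769  0.646
NaiBT  0.400  0.431  0.216  0.751  0.704
lBk    0.393  0.393  0.191  0.595  1.214
lBkT   0.309  0.383  0.077  0.521  1.382
Hip    0.330  0.330  0.113  0.634  0.736
HipT   0.236  0.306  0.063  0.635  0.742
RF     0.491  0.491  0.322  0.746  0.628
RFT    0.509  0.552  0.305  0.735  0.628
```

Each row is one (classifier, validation mode) pair — the `T` suffix marks
external-test predictions, the bare abbreviation cross-validated ones — on
a four-category ordinal dataset with the second case-study composition
(28 compounds per training class). Naive Bayes and random forest reach
~0.49 accuracy on a four-class problem (chance = 0.25) with the best Brier
losses; 1-nearest-neighbour overfits (its test AUC drops to 0.52).

Ranking the metrics against the consensus (row-mean) reference:

```python
merged = sv.merge_and_pretreat({"dataset2": matrix})
result = sv.srd_analysis(merged, reference_rule="mean", cv_folds=4,
                         cv_iterations=5, seed=0)
print(result.to_frame()[["column", "srd_norm", "crrn_q05"]].head(6).round(2))
```

```
column  srd_norm  crrn_q05
   TPR      9.38      37.5
   FNR      9.38      37.5
   ACC      9.38      37.5
    BM     12.50      37.5
   LR-     12.50      37.5
   DOR     12.50      37.5
```

The closest metrics sit at ~9% normalized SRD, far below the 5% quantile of
the random-ranking null (37.5%), i.e. they rank the eight models much more
consistently than chance would.

The same machinery is available from the shell:

```
srdeval generate --preset dataset1-imbalanced --seed 1 --out ds1
srdeval evaluate --dataset ds1 --out panel.csv
srdeval srd --matrix panel.csv --out srd.csv --plot srd.png
srdeval covat --matrix panel.csv --out covat.csv
srdeval run-all --seed 1 --out results/
```

`run-all` executes the full study — all four composition × classification
scenarios over the three case-study compositions, merged-matrix SRD of the
metrics, per-dataset SRD of the classifiers, COVAT and both ANOVAs — and
writes every artifact plus a manifest; reruns with the same seed are
byte-identical.

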