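# Methods

`lipidpanel` implements a complete biomarker-discovery analysis for
targeted lipidomics cohorts: a subjects × analytes plasma concentration
table with diagnosis labels is curated, searched for unsupervised group
structure, reduced to a small consensus marker panel, and validated
against permutation and random-panel negative controls. This note
documents the statistical model behind each stage, the defaults and why
they were chosen, and what the synthetic cohort generator does and does
not emulate.

## Synthetic cohort generator

The generator stands in for a clinical cohort of n = 94 subjects in five
diagnosis groups (depression 20, bipolar disorder 20, ADHD 12, dementia
16, controls 26) assayed for 41 lipid mediators and related metabolites
(sphingolipids, lysophosphatidic acids, endocannabinoids, nucleosides,
nucleotides, cyclic nucleotides).

Concentrations are log-normal: for subject *i* in group *g* and analyte
*j*,

    log x_ij = mu_j + beta_j (age_i − 45) + delta_j·[g = dementia] + eps_ij,
    eps_ij ~ N(0, sigma_j),

exponentiated to the concentration scale. Defaults: per-class log-scale
locations spanning several orders of magnitude, sigma_j = 0.6.

* **Disease signal.** delta_j = 0.45 log-units on seven core
  sphingolipid markers (GluCerC16:0, Cer24:0, Cer20:0, Cer16:0,
  Cer24:1, C16 sphinganine, LacCerC16:0) and 0.22 on six secondary
  sphingolipids; zero elsewhere. The magnitudes are artifact choices
  (no effect sizes are published for the motivating cohort), picked
  once so that the dementia-vs-rest contrast is clearly detectable but
  classifier accuracy stays far from saturation at n = 94.
* **Age structure.** Ages are truncated normals per group (dementia
  mean 69.9 y, controls 39.6 y restricted to 21–67 y). Seventeen
  analytes carry an age slope beta_j = 0.03 log-units/year, calibrated
  so that roughly that many reach Pearson significance in a 26-subject
  control group. `age_matched=True` draws all groups' ages from the
  control distribution.
* **Censoring.** Six analytes (sphingosine, Cer14:0, guanosine, 1-AG,
  2-AG, DHEA) have their LLOQ placed 0.385 SD above the log-mean
  (~65% of cells below LLOQ), so the group-wise >20% exclusion rule
  removes them reliably even in the 12-subject group; deoxycytidine is
  moderately censored (~18%) and survives with sub-LLOQ cells. Cells
  below half the LLOQ are unquantifiable and recorded missing; cells
  between the floor and the LLOQ keep their value with a below-LLOQ
  flag (the "verified sub-LLOQ" policy can therefore be exercised).
* **Outliers.** Each cell is multiplied/divided by 8 with probability
  0.003, i.e. ±ln 8 ≈ 3.5 sigma on the log scale — detectable but not
  trivially so for a two-sided Grubbs test at n = 94.

What the generator does **not** emulate: raw LC-MS/MS peak data, batch
or storage effects, medication covariates, sex- or BMI-linked analyte
differences, and inter-analyte correlation beyond what the shared age
and disease terms induce. Passing tests therefore show that the
pipeline recovers the structure this model plants under realistic
sample sizes, noise and censoring — not that it would perform
identically on real plasma measurements.

### The age confound

A deliberate property of the defaults: with the dementia group ~30
years older than the rest, even *after* age correction a residual age
signature remains, because correction slopes are estimated from only 26
controls and extrapolated decades beyond the control age range (the
standard error of a control-estimated slope, ~0.01 log-units/yr, maps
to ~0.3 log-units at +30 y). With the planted disease effect switched
off entirely, classifiers still separate dementia at ~80% balanced
accuracy through this channel. This mirrors the well-known limitation
of non-age-matched case-control designs; consequently the package's
fully null condition is `effect_scale=0` **and** `age_matched=True`,
and the workflow's "no structure detected" flag is validated under that
condition.

## Preprocessing

Fixed stage order: LLOQ exclusion → transform selection → iterative
Grubbs → kNN imputation → age correction.

* **Exclusion**: an analyte is dropped when its below-LLOQ fraction
  exceeds the threshold (default 0.20) in *every* diagnosis group;
  retained analytes keep verified sub-LLOQ numeric values.
* **Transform selection**: all four candidates (identity, log, square
  root, reciprocal) are tested for normality with a Kolmogorov–Smirnov
  test against a normal with the sample mean/SD (composite-null
  correction deliberately omitted; this matches common usage of the
  test in concentration data). Policy: log is preferred for
  blood-concentration data and chosen unless it is rejected at
  alpha = 0.05, in which case the reciprocal is used.
* **Grubbs**: two-sided, alpha = 0.05 (a default, configurable; the
  motivating analysis does not state its level), one removal per
  iteration, repeated while significant; removed points become missing.
* **Imputation**: k-nearest-neighbour (default k = 10, configurable)
  with Euclidean distances over mutually observed standardized analytes
  and distance-weighted averaging, via scikit-learn's `KNNImputer` on
  the standardized scale.
* **Age correction**: for analytes with a significant Pearson age
  correlation in controls, a robust (Huber M-estimator) regression is
  fitted in controls only and `slope × (age − median cohort age)` is
  subtracted from all subjects. The post-condition (control correlation
  no longer significant) is asserted in tests.
* **Rescaling**: features are mapped affinely to [0, 100] before
  clustering and ESOM training so that no analyte dominates distances.

## Unsupervised structure detection

**Ward clustering** (Euclidean, scipy linkage) with the cluster number
chosen by **progeny stability**: for each candidate k, the full data is
clustered; synthetic "progenies" are drawn per cluster by resampling
each feature independently within the cluster; progenies are
re-clustered and pairwise co-membership is recorded. The stability
score is the ratio of same-origin to different-origin co-clustering
rates, with counts pooled over a batch of iterations and a +0.5/+1
Laplace smoothing so perfectly separated data yields a large finite
score rather than a division by zero. Score > 1 indicates structure.
Defaults: 10 progenies, 100 iterations in 10 batches, 10 repeats for
the standard deviation, k ∈ {2,…,5}. Two selection criteria are
computed — greatest score, and greatest gap 2·s(k) − s(k−1) − s(k+1)
(single-neighbour difference at the range edges) — and a disagreement
resolves to the gap criterion with a warning; ties resolve to the
smaller k.

**Cluster–diagnosis association** uses the Pearson chi-squared test with
per-cell Pearson residuals (obs − exp)/√exp; |residual| > 2 flags over-
or under-represented cells.

**ESOM/U-matrix**: a Kohonen map on a 50 × 80 toroid grid (4000
neurons), weights initialized by sampling each feature's observed
values, trained online for 30 epochs with a Gaussian neighbourhood
whose radius decays from half the grid extent to 1 and a learning rate
decaying linearly 0.5 → 0.05 (conventional Kohonen defaults; the
schedule is not specified by the motivating analysis). The U-matrix
assigns each neuron the mean high-dimensional distance to its eight
toroidal grid neighbours. Cluster extraction thresholds U-heights at a
quantile (default 0.6) and takes connected low-height components
(8-connectivity with wrap-around) as basins; subjects inherit their
BMU's basin, ridge-located BMUs join the nearest basin by toroidal grid
distance. The quantile automates what is usually a visual valley/ridge
reading and is an artifact decision.

**PCA separation sweep**: every combination of transform (none, log,
sqrt, reciprocal) × centering (on/off) is scored on its first two
principal components by Mann–Whitney p-value, AUC-ROC (rank statistic,
oriented ≥ 0.5) and area under the precision–recall curve (minority
class positive) for the dementia-vs-rest contrast; the best setting
maximizes AUC with p as tiebreaker. Which rank test produced the
published separation p-value is unstated in the source procedure;
Mann–Whitney is used here. Non-centered PCA reports variance fractions
of the total (uncentered) sum of squares, which is why a magnitude axis
can "explain" ~99%.

## Consensus feature selection

For each of n_runs (default 1000) Monte-Carlo 2/3–1/3 stratified
splits, two importance vectors are computed on the training part only:

1. **Permutation importance** from a bagged ensemble of CART trees
   (default 1500 trees, √d features per split): per tree, each feature
   of the out-of-bag samples is permuted and the mean decrease in OOB
   accuracy is the importance. Negative values are clipped to 0 before
   ABC analysis.
2. **PCA r²**: squared Pearson correlation of each analyte with the
   first principal component of the training data, computed with the
   sweep-selected centering fixed once on the full data.

Each vector is partitioned by **computed ABC analysis**: items sorted
descending trace the cumulative effort/yield curve in the unit square;
set "A" ends at the curve point nearest (0, 1); set "C" starts at the
break-even item (first value at or below the mean), constrained to lie
at or after the A/B boundary (B is empty when the break-even precedes
it). The per-run set-"A" members are recorded; the consensus panel per
route takes the modal set-A size (ties → smaller) and the
most-frequent members (ties → higher mean importance, then name). The
**final panel** is the order-stable intersection of the two route
panels, in the forest route's order.

## Validation bench

Five classifier families × three feature sets (selected panel, random
equally-sized panels from the non-selected pool, all features) × two
training regimes (original, and a negative control with training rows
permuted to break the feature–label linkage), over class-balanced
Monte-Carlo splits. Splits are balanced on the smallest class (16
dementia → 11 train + 5 test per class), giving the 50% test prevalence
that makes balanced-accuracy comparisons straightforward; leftover
majority-class subjects sit out the run. Metrics (sensitivity,
specificity, PPV, NPV, precision, recall, F1, prevalence, detection
rate, detection prevalence, balanced accuracy, AUC-ROC, AUPRC) are
computed per run from the test confusion matrix (dementia positive) and
averaged over runs; ratios with zero denominators are recorded missing,
never zero, and degenerate runs are excluded from averages with a
logged count.

Hyperparameters: random forest 1500 trees with √d features per split;
kNN k = 3; SVM with RBF kernel (scores: decision values through a
logistic link); MLP with three hidden layers of 35 neurons, SGD
backpropagation, learning rate 0.1, up to 200 cycles with a
training-loss plateau stop; Gaussian naive Bayes. kNN, SVM and MLP
standardize features with a scaler fitted on the training fold inside
the pipeline — these families are scale-sensitive and without it the
MLP fails to learn even strong signal; the forest and naive Bayes are
scale-invariant and run on the raw matrix.

No test-set information reaches training at any point: importances,
scalers and classifiers are fitted on training subjects only, and a
canary test corrupts test labels to verify training outputs are
unchanged.

## Problem sizes in the shipped tests and acceptance script

The package defaults (1000 selection runs, 1000 bench runs, 1500
trees, 50 × 80 ESOM) are what an analysis of a real cohort would use.
The test suite and the acceptance script exercise the identical code
paths at reduced sizes chosen as a deliberate compute budget: the
permutation-control evaluation uses 250 (script) or 200 (tests)
balanced splits, planted-panel recovery uses 20 cohorts × 200 selection
runs with 40-tree ensembles, the scenario-ordering check uses 20 seeds
× 6 splits with 100-tree forests, and ESOM unit tests use small grids.
These sizes keep every stochastic check's Monte-Carlo error well inside
its assertion margin.

## Known limitations

* The stability-score smoothing constant (+0.5/+1) and the U-matrix
  basin quantile are pragmatic defaults, not published values.
* Consensus tie-breaking (modal size → smaller; member ties → higher
  mean importance → name) is a determinism choice; other conventions
  would occasionally pick different borderline members.
* The generator's independence of analytes conditional on age and
  diagnosis understates the correlation structure of real lipid
  panels; real-data panel stability is likely lower than on synthetic
  cohorts.
* With a non-age-matched design, part of any apparent disease signal
  can be residual age structure (see "The age confound" above); the
  package reports age-correction diagnostics so users can judge this.
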