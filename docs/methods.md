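# Methods

## Model and procedure

`rceife` selects features for two-class classification of high-dimensional
omics matrices by alternating two elimination mechanisms along a
user-supplied, strictly decreasing schedule of cluster counts
`M = (M_1 > … > M_K)`:

* **Cluster elimination.** At step `i` the active features are grouped by
  K-means into `M_i` clusters (each feature represented as its vector of
  values over the training samples). Each cluster receives a score — the
  mean held-out accuracy of a classifier trained only on that cluster's
  features, over `t` stratified random 70/30 subsamples of the training
  set — and the `M_i − M_{i+1}` lowest-scoring clusters are dropped,
  removing all their features.
* **Intra-cluster feature elimination (IFE).** Each surviving cluster with
  more than `min_cluster_size_for_ife` features loses its
  `max(1, floor(f/100 × size))` least-important features, with importance
  from a classifier fit on the cluster's subdataset (mean impurity
  decrease for the forest, |coefficient| for the linear SVM).

After both eliminations the pooled survivors are evaluated by a freshly
fitted model: trained on the outer training split restricted to the
survivors, scored on the held-out outer test split. The per-level record
is the survivor set and the full metric panel (accuracy, sensitivity,
specificity, precision, F-measure, Mann-Whitney AUC, Cohen's kappa).

The underlying assumptions: informative features come in correlated
groups that K-means can isolate when features are compared as profiles
over samples; a group's univariate-ish predictive value is measurable by
training a small classifier on it alone; and weakly contributing members
of a good group can be identified by within-group importance. Features
eliminated once never return.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `schedule` | 100, 90, 70, 50, 30, 20, 10, 5, 2 | cluster counts; head capped at the filtered feature count |
| `train_fraction` | 0.9 | outer stratified train share (test = 1 − 0.9) |
| `n_top` | 1000 | t-test filter size (smallest two-sided p-values) |
| `ttest_variant` | welch | `welch` or `pooled`; Welch is the safer default for heteroscedastic omics data |
| `t` | 10 | inner 70/30 subsamples averaged into a cluster score |
| `inner_train_fraction` | 0.7 | inner stratified train share |
| `f` | 10 | percent of features removed per eligible cluster; 0 disables IFE |
| `min_cluster_size_for_ife` | 5 | clusters at or below this size are never pruned |
| `learner` | random_forest | or `svm` (linear kernel, C = 1) |
| `n_estimators` | 100 | forest size for importance and modeling |
| `scoring_n_estimators` | = `n_estimators` | forest size for the cluster scorer; scoring needs only a coarse accuracy estimate, so a smaller forest here cuts most of the runtime (scoring dominates: roughly `sum(schedule) × t` fits per repetition) |
| `standardize` | true | z-score feature vectors before K-means |
| `kmeans_restarts` / `kmeans_max_iter` | 10 / 300 | K-means settings (k-means++ init) |
| `balance` | true | undersample the majority class before the outer split |
| `n_repeats` | 100 | repetitions aggregated into means/stds and the survival ranking |

All randomness flows from one master seed through a counter-based
derivation (`rceife.seeds.derive_seed`): every repetition, outer split,
K-means call, inner subsample and learner fit has a deterministic,
decorrelated seed, recorded in the run manifest. Identical inputs and
master seed reproduce results bit for bit.

## Design choices where the design was open

* **Inner "cross-validation".** Cluster scoring uses `t` *independent*
  stratified 70/30 random subsamples (Monte-Carlo CV) rather than `t`
  disjoint folds: disjoint 10-fold would contradict the 70/30 split ratio
  that defines the scorer.
* **Undersampling before the outer split**, once per repetition, so both
  the training and test sides stay balanced and AUC is always defined.
* **Stratified outer split.** The outer 90/10 split is stratified per
  class (floor of the fraction to train, remainder to test, with a guard
  that moves one sample back if a class's test side would be empty);
  otherwise small minorities can leave the test side single-class.
* **IFE rounding.** `floor(f/100 × size)` alone removes nothing from
  clusters of size 6–9 at `f = 10`; the `max(1, ·)` floor guarantees
  progress. Clusters never shrink below one feature.
* **Tie rules**, all deterministic: equal t-test p-values keep original
  column order; equal cluster scores eliminate the largest cluster id
  first; equal importances remove the larger feature id first; equal
  survival scores rank by feature id ascending.
* **Undefined metrics** (zero denominator, e.g. precision with no
  positive predictions) are reported as missing and excluded from
  repetition means, with the count of contributing repetitions
  (`n_defined`) reported — averaging zeros would bias the summaries.
* **Constant features** get p = 1 in the filter (sort last) and a zero
  vector after standardization; the learners tolerate constant columns.
* **Capped schedules.** A schedule head exceeding the filtered feature
  count is capped (with a warning), preserving strict decrease; K-means
  returning fewer effective clusters than the next level skips that
  elimination step with a warning rather than failing.
* **Missing values are rejected** at load with the offending cells named;
  silent imputation would change scores invisibly.

## The synthetic generator

`rceife.synthetic` draws two-class Gaussian matrices in which planted
blocks of features are equicorrelated (pairwise correlation exactly `rho`,
via the one-factor construction `sqrt(rho)·z_shared + sqrt(1−rho)·z_own`)
and carry a between-class mean shift of `effect` within-class standard
deviations; all remaining features are independent noise with zero shift.
Defaults encode the study condition used throughout the tests: 60 + 60
samples, 2,000 features, three blocks of 10 informative features with
effect 1.5 SD and `rho = 0.6`.

This emulates the correlation-block structure and signal strength of real
expression panels at desk scale, but not: heavy-tailed or count-valued
distributions, compositional constraints and zero inflation of
metagenomic abundances, batch effects, or feature-count regimes of full
microarrays (tens of thousands). Passing tests therefore demonstrate that
the engine recovers block-structured Gaussian signal and behaves at
chance on permuted labels — not clinical performance on any particular
real dataset.

## Problem sizes in the tests and acceptance script

Unit tests run on matrices of tens of samples and at most a few hundred
features with small forests (10–30 trees) and `t` of 2–10. The
end-to-end checks use the full study condition (60 + 60 × 2,000) at
`t = 10` with the default 100-tree forests for importance and modeling —
importance fidelity decides which features IFE removes, and both
planted-feature recovery and the cross-aggregate consistency of the
ranked list degrade visibly when it is scaled down — while the cluster
scorer, which needs only a coarse accuracy estimate but accounts for
nearly all forest fits, uses 6–15 trees. The null control (permuted
labels) is fidelity-independent by symmetry and runs at the cheapest
scale. `scripts/acceptance.py` runs the study condition with the same
split: 100-tree importance/modeling forests, a 15-tree scorer, `t = 10`,
6 repetitions for the metric summary, plus two independent
10-repetition aggregates (6-tree scorer) for the ranked-list
consistency readout.

## Known limitations

* Cluster scores from accuracy on 30% of a small training set are coarse
  (granularity 1/|d_test|); with few samples many clusters tie and the
  deterministic tie rules, not the data, decide eliminations.
* The t-test filter is univariate: informative features with no marginal
  shift (pure interactions) are discarded before clustering.
* Survival ranking counts levels survived, so it saturates: features that
  persist to the end in every repetition all receive the maximal score
  and only the tie rule orders them.
* Runtime is dominated by `(sum of schedule levels) × t` forest fits per
  repetition; large schedules on many repetitions call for reduced
  `n_estimators` or the SVM learner.
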