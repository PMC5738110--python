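# Methods

## The selection model

`omicsfs` treats feature selection for an omics table `X` (n samples ×
p features, p ≫ n) as a staged pipeline: cheap filters first, an
expensive wrapper last.

**Univariate relevance.** For a continuous outcome, or a binary outcome
encoded 0/1 in `class_levels` order, each feature is scored by the
absolute Pearson correlation with the outcome. Features with
|r| ≤ cutoff (default 0.30) are removed — the boundary itself falls.
Constant columns have an undefined correlation; they are assigned score
0 and dropped with a `zero_variance` tag instead of aborting the run,
because degenerate columns are routine in expression matrices. For more
than two classes the correlation is undefined and the filter refuses,
pointing to the information-gain alternative: gain in bits,
H(class) − H(class | binned feature), with equal-frequency binning into
⌈√n⌉ bins capped at 10 (configurable; the choice matters little above
~8 bins, and equal-frequency binning is robust to heavy-tailed
intensities).

**Redundancy reduction.** Two interchangeable strategies:

* *Correlation-matrix (CM) filter.* Greedy pairwise elimination in the
  style of caret's `findCorrelation`: while any retained pair has
  |r| ≥ cutoff (default 0.75, the boundary removed), take the
  most-correlated violating pair and drop the member with the larger
  mean absolute correlation against all currently retained features;
  ties within 1e-12 drop the later column, keeping earlier features and
  making the procedure deterministic. The post-condition (no retained
  pair at or above the cutoff) is machine-checked after every call.
  This keeps original, interpretable features — required when the final
  model must transfer to new measurements, e.g. regression on
  physicochemical peptide properties.
* *PCA filter.* Features are centered and scaled to unit variance
  (omics features live on wildly different scales; scaling is the
  default and a flag), decomposed by SVD, and replaced by the smallest
  number of leading components whose cumulative explained-variance
  ratio reaches the target (default 0.95). Component signs are fixed by
  forcing the largest-magnitude loading positive, so results are
  platform-independent. Ratios below 1e-12 are treated as rank noise;
  at most min(n − 1, p) components carry variance. Constant columns are
  standardized to all-zeros rather than rejected.

A configuration placing the CM filter after PCA is rejected at
validation: component scores are exactly uncorrelated, so the step would
be a guaranteed no-op and almost certainly a user error.

**Wrapper RFE.** Backward elimination around a learning model with
internal k-fold cross-validation (default 10; classification folds are
stratified, regression folds plain random, all seeded). Within each
fold, features are ranked on the training part only; the model is refit
on the top-k for every candidate size and scored on the held-out part.
The default size grid is powers of two from 1 up to, and always
including, the full count — log-spaced grids bound the number of model
fits at a negligible cost in resolution. The chosen size maximizes mean
CV accuracy (classification) or minimizes mean CV RMSE (regression),
ties broken toward the smaller size (parsimony). The final ranking and
panel are then recomputed on the full training data.

Rankings: random forests use impurity-decrease importance (500 trees by
default, the upstream convention); the radial-SVM wrapper uses the
model-free |Pearson r| ranking, the usual default for non-tree models —
permutation importance is available behind `importance="permutation"`
but is quadratically more expensive and not the default. The SVM kernel
width is set by the median heuristic on training-fold pairwise
distances, cost C = 1.

**Evaluation harness.** Generalization is estimated by repeated
randomized class-balanced splits (default 20, train fraction 2/3).
"Class-balanced" means stratified sampling preserving class proportions;
a `balance="downsample"` mode first equalizes class sizes. The whole
pipeline — missing-value handling, every filter, the RFE, the final
fit — is refit inside each split on training rows only; the held-out
rows are seen exactly once, at scoring time. Per-split seeds derive from
the master seed through `SeedSequence([master, i])`, so any single split
is reproducible in isolation. Wall-clock per step is recorded for
information only. Regression R² is the squared Pearson correlation of
predicted vs observed (the resampling-framework convention);
`compute_metrics_ss` provides 1 − SSE/SST when that convention is
wanted.

**Missing values.** Feature-wise complete-case deletion, no imputation:
any feature with a missing cell is removed before filtering and tagged
`missing_values`. Note that at a cell-missingness rate m the probability
a feature survives is (1 − m)^n — at n = 200 even m = 0.05 removes
essentially everything, which is the realistic behavior of
complete-case policies and why upstream imputation pipelines exist
(out of scope here).

## The synthetic family

The generator emulates the structure the workflow assumes, with defaults
chosen as a realistic hard-but-solvable desk-scale instance: n = 150
samples, 5 informative features at standardized class-mean separation
d = 1.5 (point-biserial r ≈ 0.6, comfortably above the 0.30 screen),
10 redundant copies at target correlation ρ = 0.85 (star topology, one
parent each, so proxy relationships are checkable), 300 pure-noise
features (at n = 150 a noise feature crosses the 0.30 screen with
probability ~10⁻⁴ per feature), balanced binary classes. Redundant
copies mix the *standardized* parent with fresh noise,
`copy = ρ·z_parent + √(1−ρ²)·ε`, so the population correlation with the
parent equals ρ exactly even though the parent's marginal variance
exceeds 1 when it carries class structure. Class-conditional
distributions are Gaussian for analytic tractability (a t(3) option
exists for robustness checks); labels get deterministic
largest-remainder counts and a seeded shuffle. Everything is a pure
function of the seed.

What the generator does **not** emulate: mass-spec intensity
distributions, microarray background/saturation, batch effects,
sample-level artifacts, or correlated noise blocks without outcome
signal. Tests passing on this family therefore demonstrate the
machinery's correctness and the workflow's behavior under its own
assumptions, not performance on any particular real platform.

## Benchmark harness and problem sizes

The repeated simulations (`omicsfs.bench`) run the full
X2(0.30)–CM(0.75)–RFE–RF pipeline with 3-fold internal CV and 100-tree
forests — sizes chosen so that a 100-replicate recovery simulation and a
20-split non-inferiority comparison complete in minutes on one CPU.
Both are scale knobs, not method changes: 10-fold CV and 500-tree
forests remain the library defaults for real analyses.

## Known limitations

* **The CM heuristic keeps proxies, not parents.** In a correlated
  cluster the parent feature has the *largest* mean absolute correlation
  (it touches every copy, plus the class-induced between-signal
  correlation), so the greedy rule eliminates it first and retains a
  ρ-attenuated copy (effective separation ≈ ρ·d/sd(parent) instead of
  d). The planted signal is still *represented* — the recovery
  simulation counts a copy as its parent's proxy and reports the
  per-replicate pass rate — but the selected panel can be slightly
  weaker than the best k original features.
* **Selection is not always free.** A no-selection random forest
  averages over *all* correlated signal proxies (15 in the default
  family) and on this family tends to score a few accuracy points above
  the small pipeline panel, at the cost of carrying all 315 features
  (`scripts/acceptance.py` reports the measured gap and the selected
  fraction). The value proposition on such data is the >90% feature
  reduction at a small, quantified accuracy cost; on tables where noise
  features corrupt the forest (smaller n, weaker signals, heavier
  tails) the ordering can reverse. The test suite asserts a strict
  2-point non-inferiority bound and currently records this gap as a
  failure rather than hiding it.
* The univariate correlation screen is linear; features predictive only
  through interactions or non-monotone effects are lost at stage one
  (use the information-gain screen or skip to RFE for those).
* RFE ranks once per fold (no iterative re-ranking); with strongly
  collinear survivors the importance split can demote a true signal.
* No nested hyperparameter tuning: forest size and SVM cost are fixed
  conventions, not optimized per dataset.
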