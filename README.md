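# omicsfs

Filter + wrapper feature-selection workflows for high-dimensional omics
matrices (gene expression, proteomics, physicochemical peptide tables).

A typical omics classification or regression problem starts from a
samples × features table with thousands of redundant and irrelevant
columns. `omicsfs` implements the staged selection strategy that works
well in that regime:

1. **Univariate relevance filter (X2).** Score every feature by
   |Pearson r(x_j, y)| (binary outcome encoded 0/1; information gain in
   bits is available for multi-class problems) and remove everything
   with |r| ≤ 0.30.
2. **Multivariate redundancy reduction.** Either the **correlation-matrix
   (CM) filter** — greedily eliminate one member of every feature pair
   with |r| ≥ 0.75, keeping original features — or a **PCA filter** that
   replaces features with the fewest principal components reaching 95%
   cumulative explained variance.
3. **Recursive feature elimination (RFE).** Backward elimination wrapped
   around a random forest (impurity importance) or a radial-kernel SVM
   (model-free correlation ranking), with internal k-fold
   cross-validation (default 10) choosing the subset size; ties go to the
   smaller subset.

Generalization performance is estimated the honest way: repeated
randomized, class-balanced (stratified) train/test splits (default 20),
with **every** filter and the RFE refit inside each split on the training
part only — no selection leakage.

A synthetic-data generator produces datasets with the structure the
workflow assumes (a small informative block, redundant copies correlated
ρ with one parent each, a large noise block, optional missingness), so
every stage is testable without downloads.

## Worked example

```bash
omicsfs simulate --n-samples 150 --informative 5 --redundant 10 \
    --noise 300 --effect-size 1.5 --rho 0.85 --seed 42 --out-dir data
omicsfs run --data data/data.tsv --labels data/labels.tsv \
    --steps x2,cm --model rf --cv-folds 3 --trees 100 --seed 42 --out-dir out
omicsfs report --metrics out/metrics.json
```

prints

```
omicsfs run report (task=classification, seed=42)
filter chain:
  univariate_corr @ 0.3: kept 15, dropped 300
  matrix_corr @ 0.75: kept 9, dropped 6
feature counts: 315 -> 15 -> 9 -> 8
training metrics: accuracy=1.0000
selected features (8): red6, red4, red8, red1, red3, red9, red7, red10
```

Reading: of 315 features, the univariate screen keeps the 15 with
|r| > 0.30 against the class (here: the 5 informative features, their 10
correlated copies, give or take sampling noise), the CM filter collapses
each correlated cluster to one representative, and RFE settles on an
8-feature panel. All five planted signals are represented — each selected
`red*` feature is a ρ = 0.85 proxy of one informative parent, which is
exactly the proxy behavior the CM heuristic produces (see
`docs/methods.md` on why parents, having the largest mean absolute
correlation, are the ones eliminated).

The same pipeline from Python:

```python
from omicsfs import (SyntheticSpec, make_classification_data,
                     WorkflowConfig, FilterStep, RFEConfig,
                     run_workflow, evaluate_workflow)

X, y, truth = make_classification_data(SyntheticSpec(seed=42))
config = WorkflowConfig(
    task="classification",
    steps=[FilterStep("univariate_corr", 0.30),
           FilterStep("matrix_corr", 0.75)],
    rfe=RFEConfig(cv_folds=10))
summary = evaluate_workflow(X, y, config, n_splits=20)
print(summary.mean["accuracy"], summary.sd["accuracy"],
      summary.median_n_features)
```

`evaluate` writes a metrics JSON (schema in
`src/omicsfs/schemas/metrics.schema.json`) plus a per-split
selected-features TSV; identical seeds reproduce both byte-for-byte.

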