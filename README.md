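# copredict

Interpretable rule-based analysis of multi-cohort expression data: rough-set
rule models, cross-cohort merging, co-predictive networks and subgroup
dissimilarity testing — exercised end to end on synthetic cohorts.

## What it does

1. **Synthetic cohorts** (`copredict.synthetic`) — multi-cohort case/control
   expression matrices with graded case subtypes, per-subtype mean shifts,
   gene pairs correlated in cases but not controls, cohort offsets and
   Gaussian noise; fully deterministic under a seed.
2. **Preprocessing** (`copredict.preprocess`) — equal-frequency three-level
   discretization learned on training data only, and class balancing by
   undersampling with the sampled-out objects retained.
3. **Feature selection** (`copredict.mcfs`) — Monte Carlo feature ranking by
   relative importance over decision trees on random attribute subsets,
   knee-point (critical-angle) thresholding, model-quality threshold
   adjustment, and cross-cohort ranking merges on a rescaled RI scale.
4. **Rule learning** (`copredict.rules`) — object-related Johnson reducts,
   IF-THEN rules with support/accuracy/coverage/hypergeometric-p statistics
   recalculated on the full table, support-weighted standard voting,
   stratified 10-fold CV, and Benjamini–Hochberg rule filtering.
5. **Model merging** (`copredict.merge`) — per-cohort tables stacked under
   their own discretization cuts; identical rules unified with summed
   supports and unioned support sets, then all statistics renormalized to
   the merged cohort.
6. **Co-predictive networks** (`copredict.network`) — (feature, level) nodes,
   edges weighted by Σ RS×RA over rules containing both conditions, min-max
   normalization, hub detection, top-N filtering, exact 1-D 2-means top
   co-predictor selection and functional term fractions.
7. **Subgroup dissimilarity** (`copredict.subgroups`) — rules mapped to
   clinical subgroups through support sets, subgroup subnetworks compared by
   betweenness-centrality distance averaged over balanced rule resamples,
   with a label-permutation null and Kendall tau-b distance matrices.
8. **Pipeline** (`copredict.pipeline`, `copredict.cli`) — orchestration with
   per-stage manifests and deterministic per-stage seeds derived from one
   master seed.

## CLI

```sh
copredict simulate --spec spec.yaml --out data/ --seed 1
copredict select-features --values data/cohort1_values.tsv \
    --meta data/cohort1_meta.tsv --out ranking.tsv --seed 1
copredict learn --values data/cohort1_values.tsv --meta data/cohort1_meta.tsv \
    --features ranking.tsv --folds 10 --seed 1 --out model/
copredict network --model model/ --cls case --top-nodes 30 --out net/
copredict subgroups --model model/ --meta data/cohort1_meta.tsv \
    --n-perm 500 --n-balance 20 --seed 1 --out dist/
copredict run --config pipeline.yaml --out results/   # full pipeline
```

A pipeline config is YAML with stage sections (`synthetic` or `cohorts`,
`mcfs`, `adjust`, `learn`, `fdr`, `network`, `subgroups`) and a master
`seed`; see `tests/test_pipeline.py` for a worked example.

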