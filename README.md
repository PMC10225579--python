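# dgcna — differential gene co-expression network analysis

`dgcna` is a Python package for asking how gene–gene *co-expression* — not
gene expression itself — differs between two biological conditions in bulk
RNA-seq data (case vs. control cohorts, e.g. a disease and a matched normal
group).  It implements the full analysis chain as a library with a thin CLI:

1. **Preprocessing** — CPM normalization, a global-average transcript
   abundance filter, a 10-million-read sample depth filter, optional
   restriction to protein-coding biotypes, and a `log2(CPM+1)` variance
   stabilizer.
2. **Co-expression modules** (per group) — inverse-gamma variance filtering,
   automatic soft-threshold selection against the scale-free topology
   criterion, unsigned weighted adjacency `a = |r|^β`, topological overlap
   (TOM) similarity, average-linkage clustering with an adaptive tree cut,
   intramodular-connectivity hub genes, and module stability under 100×
   subsampling of 70% of samples.
3. **Differential co-expression** — pairs co-expressed in ≥ 1 condition are
   tested with Fisher's Z for a correlation difference,
   `z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))`; BH-significant pairs
   are *differential co-expressed links* (DCLs), and genes with more
   incident DCLs than a Binomial(n_links, p̂) null at the global DCL rate p̂
   predicts are *differential co-expressed genes* (DCGs), with
   subsample-stability scores.
4. **Network comparison** — pairwise adjusted mutual information (exact
   permutation-model chance correction) between differential networks from
   different datasets, plus shared-DCL gene reports.
5. **Enrichment** — hypergeometric over-representation analysis of any gene
   list against GMT gene-set collections with BH FDR control.
6. **Prediction** — condition classification from expression of chosen
   feature gene sets with gradient-boosted trees (binary logistic
   objective), scored by mean AUC and mean test error over ten rounds of
   stratified 5-fold cross-validation.

A first-class synthetic-data generator plants known co-expression modules
(latent-factor construction with configurable within-module correlation)
and known differential pairs (configurable per-condition correlations,
including differential *hub* stars) in negative-binomial counts, so every
stage is validated against ground truth.  See `docs/methods.md` for the
models and numerical choices.

The core stages are also exposed as scikit-learn-style estimators —
`CoexpressionModules` (a clustering estimator: `fit(X)` → `labels_`,
`hubs_`, `beta_`) and `DifferentialCoexpression` (`fit(X, y)` → `dcls_`,
`dcgs_`, `network_`) — operating on samples × genes matrices.

## Worked example

```python
from dgcna import (
    SimulationParams, generate_dataset, run_coexpression_chain,
    ConditionedExpression, differential_coexpression,
)
from dgcna.preprocess import vst
from dgcna.simulate import star_pairs

params = SimulationParams(
    n_genes=160,
    n_samples_per_condition=(70, 70),
    module_sizes=[40, 40],            # two planted co-expression modules
    within_module_cor=0.85,
    planted_pairs=star_pairs(100, [101, 102, 103, 104], r1=0.8, r2=0.0),
    seed=42,
)
counts, truth = generate_dataset(params)
expr = vst(counts)

coexpr = run_coexpression_chain(expr, var_filter_p=None)
print("beta:", coexpr.beta_used)
print("module sizes:", coexpr.assignment.module_sizes)
print("module 1 hubs:", coexpr.assignment.hubs[1])

cond = ConditionedExpression.from_expression(expr, "cond1", "cond2")
net = differential_coexpression(cond)
print("tested pairs:", len(net.pairs), "| DCLs:", len(net.dcls), "| DCGs:", net.dcg_genes)
print("planted hub:", truth.planted_hub_genes)
```

Output:

```
beta: 6
module sizes: {2: 40, 1: 40}
module 1 hubs: ['G000066', 'G000052', 'G000069', 'G000063', 'G000076']
tested pairs: 1872 | DCLs: 12 | DCGs: ['G000101', 'G000102', 'G000103', 'G000104', 'G000105']
planted hub: ['G000101']
```

Both planted 40-gene modules are recovered exactly (soft threshold β = 6 via
the scale-free criterion), and the planted differential hub `G000101` —
wired to four partner genes at r = 0.8 in condition 1 and r = 0 in
condition 2 — is called a DCG together with its four star leaves, out of
1,872 co-expressed pairs tested.  The 12 DCLs are the four planted
hub–leaf links plus the leaf–leaf links they induce (leaves of a shared hub
correlate at r² ≈ 0.64 in condition 1).

The same analysis is available from a shell:

```bash
dgcna simulate --n-genes 160 --module-sizes 40,40 --seed 42 --out-dir data/
dgcna coexpr --counts data/counts.tsv --metadata data/metadata.tsv --no-var-filter --out-dir coexpr/
dgcna diffcoexp --counts data/counts.tsv --metadata data/metadata.tsv --out-dir diffcoexp/
dgcna run-all --config config.yaml    # the whole pipeline, YAML-driven
```

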