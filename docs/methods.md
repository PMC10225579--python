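# Methods

`dgcna` implements a two-condition differential gene co-expression analysis
for bulk RNA-seq counts, together with a synthetic-data generator that plants
known structure so every stage can be validated end to end.  This note
records the models, the numerical choices, and what the synthetic validation
does and does not demonstrate.

## Preprocessing

Counts are normalized to counts per million (CPM, per-sample scaling to a
library of 10^6).  Three filters precede network analysis:

* **Global-average transcript filter** — a transcript is removed when its
  total count across samples is strictly below the mean of those totals over
  transcripts; ties are retained.  An alternative per-sample reading
  (survive if the count reaches the sample's own mean in ≥ 1 sample) is
  available via `per_sample=True`.
* **Sample depth filter** — samples with fewer than 10 million total reads
  (default, configurable) are dropped; the comparison uses raw counts, since
  CPM totals are constant by construction.
* **Biotype filter** — restriction to protein-coding transcripts when an
  annotation table is supplied; unannotated genes resolve to a sentinel
  label and are removed under the default keep-set.

The variance-stabilizing transform is `log2(CPM + 1)`, with CPM recomputed
from the current (filtered) matrix so library sizes always reflect retained
genes.  Every operation records itself in a provenance list and never
mutates its input.

## Co-expression modules

The per-group chain follows the weighted co-expression recipe:

1. **Variance filter.** Per-gene sample variances are fit by maximum
   likelihood to an inverse-gamma distribution (location 0); a gene's p is
   the upper-tail probability of its variance under the fit, and genes with
   p ≤ 0.1 (default) — the most variable tail — are kept.  For data whose
   gene variances are homogeneous by construction (our simulations), the fit
   is nearly degenerate and the filter keeps an arbitrary fraction, so the
   planted-structure tests run with the filter disabled (`var_filter_p=None`);
   this is a property of such data, not of the filter.
2. **Soft threshold.** For each candidate power β in 1..20 the unsigned
   adjacency `a = |r|^β` is formed and the scale-free fit index computed:
   connectivities `k_g = Σ_h a_gh` are binned (10 equal-width bins),
   `log10 p(k)` is regressed on `log10 k̄`, and R² is negated when the slope
   is positive.  The selected β is the smallest one with R² ≥ 0.8 *and* mean
   connectivity ≥ 1 — the connectivity floor prevents the degenerate
   high-power regime (all adjacency ≈ 0) from trivially fitting a line.
   When no candidate qualifies, the chain falls back to the standard
   sample-size default power for unsigned networks (6 for n > 40, 7 for
   31–40, 8 for 21–30, 9 otherwise), which is what practitioners do when the
   scale-free criterion fails; the selector still reports the argmax-R² β
   with `criterion_met=False`.
3. **Topological overlap.**
   `TOM_gh = (L_gh + a_gh) / (min(k_g, k_h) + 1 − a_gh)` with
   `L_gh = Σ_{u≠g,h} a_gu a_uh`; unit diagonal; symmetric to 1e−12 by
   construction.
4. **Module detection.** Average-linkage hierarchical clustering of
   `1 − TOM` followed by an adaptive tree cut.  Tight modules complete their
   internal merges low in the dendrogram while background genes and
   inter-module "glue" join near the top, so the sorted merge heights show a
   wide gap between regimes.  The tree is cut at the midpoint of the largest
   gap, considering only gaps with at least `min_module_size − 1` merges
   below them (a module of m genes needs m − 1 merges below the cut; this
   also ignores near-duplicate artifacts at the bottom of the tree).  When
   no eligible gap reaches `min_gap = 0.02`, the tree is declared
   structureless and every gene is labeled 0.  The threshold sits two orders
   of magnitude above the gap ceiling measured on pure-noise data (~1e−4).
   Clusters below `min_module_size = 30` are labeled 0; survivors are
   relabeled 1..K by decreasing size.  The cut is a deterministic variant of
   dynamic tree cutting: it splits weakly glued module pairs that a single
   static cut at a fixed height cannot separate.  A known limitation is a
   dataset that is one single tight module with no background: with no gap
   between regimes it is reported as structureless.
5. **Hubs.** Per module, genes are ranked by intramodular connectivity
   `k_within(g) = Σ_{h ∈ module(g)} a_gh` (self excluded); the top
   `n_hubs = 5` are reported, ties broken lexicographically.
6. **Stability.** `module_stability` redraws `floor(0.7 n)` samples without
   replacement 100 times, reruns the entire chain from counts, and reports
   the distribution of module counts (the headline accuracy is the modal
   count's frequency), per-rank size mean ± sd, and per-gene hub recovery.
   70% subsampling without replacement matches the resampling design the
   analysis emulates; a classical with-replacement bootstrap would duplicate
   samples and inflate correlations.

Pearson correlation is the default throughout; Spearman is available via
`method="spearman"`.

## Differential co-expression

Given expression split into two conditions (n₁, n₂ ≥ 4):

* **Gating.** All gene pairs are tested per condition (two-sided p from
  `t = r√((n−2)/(1−r²))` on n−2 df); BH runs over all pairs per condition,
  and a pair is *co-expressed* in a condition iff |r| ≥ 0.5 and q ≤ 0.1.
  Pairs co-expressed in at least one condition form the tested universe.
* **DCLs.** For each retained pair,
  `z = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3))` with a two-sided
  normal p; |r| = 1 is clamped to 1 − 1e−15 before `atanh`.  BH runs over
  retained pairs only (only they were tested); pairs with q ≤ 0.1 are
  differential co-expressed links.  Classes: *same-signed* (co-expressed in
  both conditions, same sign), *switched-opposite* (both, opposite signs),
  *diff-signed* (one condition only).
* **DCGs.** With global rate `p̂ = #DCLs / #retained pairs`, a gene with
  `n_links` incident retained pairs and `n_dcls` incident DCLs gets
  `p = P(X ≥ n_dcls)`, `X ~ Binomial(n_links, p̂)`; BH over all linked
  genes; q ≤ 0.1 calls a DCG.  The global-rate null means DCG calling is
  only informative when the tested universe contains stable co-expressed
  pairs (e.g. module pairs preserved across conditions); if every retained
  pair is differential, p̂ = 1 and nothing can be enriched.
* **DCG stability.** 100 reps subsample each condition independently at 70%
  (preserving the group ratio; a joint mode exists) and rerun the whole
  chain; the score is the fraction of reps in which a gene is re-called.

All four thresholds (rth, q_coexp, q_dcl, q_dcg) default to 0.5/0.1/0.1/0.1
and are configurable; BH is used wherever an FDR is required.

## Network comparison

Two differential networks are compared as binary labelings of a shared edge
universe: the union of pairs tested in any network, restricted to genes
present in every dataset; a pair is labeled 1 where it is a DCL.  Adjusted
mutual information is computed from the 2×2 contingency table with the
*exact* expected MI under the permutation model (hypergeometric expectation,
log-factorials via `gammaln`), normalized by the mean of the two entropies.
AMI is 1 for identical non-constant labelings, ≈ 0 for independent ones, and
invariant to label renaming; two constant labelings are defined as 0 with a
warning.  An alternative mode labels genes by the connected component of the
DCL graph (isolated genes = 0) and compares those clusterings.  Shared-DCL
gene lists (genes incident to ≥ 1 DCL in both networks) accompany every
pairwise AMI.

## Over-representation

Standard hypergeometric ORA over GMT collections: with universe size N, set
size K (after intersection with the universe), query size n and overlap k,
`p = P(X ≥ k)` for `X ~ Hypergeom(N, K, n)`; BH across sets; q ≤ 0.05
default.  The universe is the gene set entering the relevant analysis stage,
not the genome.  Query genes outside the universe are dropped with a
warning.

## Prediction

Condition labels are predicted from expression of a feature gene set with a
gradient-boosted tree classifier (binary logistic objective; 100 trees,
depth 4, learning rate 0.1 — fixed moderate defaults, no tuning, for
determinism and desk-scale runtime).  Evaluation is ten rounds of stratified
5-fold cross-validation with a fresh seeded partition per round;
stratification matters because case/control cohorts are typically
imbalanced.  Reported metrics per feature set: mean ± sd of held-out AUC
(Mann–Whitney formulation, ties ½) and of the misclassification rate at
probability 0.5.

## Synthetic data

`generate_dataset` draws, per gene and sample, a latent log-scale signal:
module gene g in module m gets `x = √ρ·f_m + √(1−ρ)·ε` with a shared
per-sample factor `f_m ~ N(0,1)`, so co-members correlate at ρ; background
genes are pure noise.  Planted differential pairs override the background: a
pair is bivariate normal with correlation r₁ in condition 1 and r₂ in
condition 2; when pairs share a gene (a planted differential hub), the
partner is drawn conditionally as `r·x + √(1−r²)·η`, which reduces to the
bivariate construction for disjoint pairs.  Counts are negative binomial
with mean `L_s·exp(μ + x)`, log-normal library sizes
(`log L ~ N(0, 0.2²)`), dispersion α.

Defaults: `mean_log_expression = 6.5` (≈ 650 counts per gene — a
well-expressed transcript) and `nb_dispersion = 0.01` (typical for
well-expressed genes in bulk RNA-seq).  At these settings the NB measurement
noise (variance ≈ α + 1/μ ≈ 0.012 on the log scale) attenuates the realized
log-CPM correlation by under 2%, so planted correlations are recovered
within the documented tolerances.  Randomness is hierarchical: every gene,
factor and sample uses a named substream of one top-level seed, so enlarging
the gene set never perturbs earlier genes' draws, and a fixed seed
regenerates the data bit-identically.

What the generator does *not* emulate: heterogeneous baseline abundance
across genes (every gene shares μ), gene-length effects, batch effects,
covariates, or variance heterogeneity beyond the NB mean–variance relation.
Two consequences for interpreting passing tests: the inverse-gamma variance
filter and the global-average abundance filter are scientifically
meaningless on such data (they would remove an arbitrary subset), so the
planted-structure validations run with both disabled, and each filter is
instead validated directly against hand-computed and enumeration oracles.
A further simulation artifact worth knowing: when planted modules make up a
large fraction of the transcriptome (half, in the recovery tests), CPM
normalization couples the modules negatively (r ≈ −0.4 between modules),
which an unsigned network turns into weak glue between them — this is what
motivated the adaptive tree cut above.

## Pipeline

`run_all` executes preprocess → per-group co-expression (each condition and
the pooled samples) with optional stability → two-condition differential
co-expression with optional DCG stability → optional ORA of module and DCG
gene sets → optional prediction over derived feature sets (co-expression
hubs, DCGs, their union, the differential-network genes) and user-supplied
lists.  Group-exclusive module genes and hubs (set differences between the
two conditions) are reported.  A manifest records the config snapshot and
the SHA-256 of every output, making bit-reproducibility checkable; all
randomness flows from the single config seed through named substreams.
Groups below 20 samples trigger a best-practice warning.

## Validation problem sizes

The shipped validation uses desk-scale problems chosen to make the measured
properties sharp: 10,000 simulated correlation pairs for type-I calibration,
200 independent datasets for DCL power at group sizes 70/200, a 200-gene /
200-sample dataset with two 50-gene modules (ρ = 0.85) for recovery and
100-rep stability, 100 random matrices (≤ 8 genes) for the TOM oracle,
universes ≤ 25 for exact hypergeometric enumeration, and a 220-gene pipeline
run with three planted 6-leaf differential hubs for the end-to-end check.
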