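# Methods

This note records the statistical procedures the package implements, the
conventions chosen where the method leaves room, and what the synthetic
cohorts do and do not establish.

## Differential APA calling

PDUI values are bounded proportions with substantial missingness (DaPars2
output is sparse), so group means are taken over non-missing values only,
and events with fewer than `min_per_group = 3` non-missing values in any
group are excluded rather than imputed — imputation would fabricate 3′-UTR
signal. The effect size is ΔPDUI = mean(group A) − mean(group B) with
A = responders fixed by convention; ΔPDUI > 0 therefore reads "shortened
in non-responders" and all direction labels derive from that sign.

Significance comes from a label-permutation test: labels are permuted
jointly across all events (preserving between-event correlation), and the
two-sided empirical p is `(1 + #{|Δ_perm| ≥ |Δ_obs|}) / (B + 1)` — the
add-one estimator keeps p > 0. When the number of distinct group-A subsets
C(n, n_A) does not exceed B, the test switches to exact enumeration with
p = #{|Δ| ≥ |Δ_obs|} / C(n, n_A), which matches the brute-force oracle in
the tests identically. Comparisons use an absolute slack of 1e−12 so
floating-point ties count as ties.

Calling requires |ΔPDUI| ≥ 0.1 (boundary inclusive) and p < 0.05
(exclusive). Benjamini–Hochberg q-values are always reported, and
`use_fdr=True` switches the second criterion to q < 0.05; the default uses
the raw permutation p, reading the published criterion as a raw p-value
threshold with FDR reported alongside. Subgroup analyses (TA = T-cell
activation, TS = suppression/depletion, TN = naive) run the same machinery
one-vs-rest; gradient detection reports events whose three subgroup means
are strictly monotone in the order TA → TS → TN with range ≥ 0.1.
Subgroup assignment labels each patient by the T-cell state class with the
largest summed population fraction, breaking exact ties by the fixed
priority TA > TS > TN.

## ATF network and master factors

Correlation edges are Spearman correlations between an APA factor's
expression and a differential event's PDUI over pairwise-complete samples,
kept at p < 0.05 and |rho| ≥ 0.3. The rho cutoff is a package default
(the source method names only the correlation analysis); it keeps the
network sparse and is configurable, including 0. PPI edges are restricted
to node pairs inside the factor ∪ event-gene universe; parallel
correlation + PPI evidence merges into a single edge carrying both
attribute sets.

The twelve topology measures follow the cytoHubba definitions, computed on
the largest connected component (other nodes score 0 and rank last):
Degree; Betweenness and Stress from all-pairs shortest paths (Stress
counts paths, Betweenness fractions them); Closeness in the harmonic form
(sum of reciprocal distances — robust to disconnection); EcCentricity as
1/eccentricity; Radiality as Σ(diameter + 1 − d(v, u))/(n − 1); local
ClusteringCoefficient; MNC as the order of the largest component of the
open neighborhood subgraph and DMNC as E/V^1.7 on that component; MCC as
Σ (|C| − 1)! over maximal cliques containing the node; BottleNeck from
single-source BFS shortest-path trees with deterministic neighbor order
(sorted node id), a node scoring once per tree in which its subtree holds
≥ n/4 nodes; EPC by Monte-Carlo edge percolation (1000 graph samples,
retention 0.5, seeded) scoring the expected number of nodes still
connected. Exact clique enumeration is guarded by a configurable node
bound (default 2000); beyond it the suite refuses rather than silently
degrading.

Aggregation into master factors uses a Borda count — the sum of the
twelve per-algorithm ranks, smaller better, over factor nodes — with ties
broken by Degree then lexicographically. The source method does not state
how twelve rankings became a top-10 list; Borda is the package's choice
(simple, deterministic, order-invariant), with `intersection-topN`
available as an alternative.

## The scoring system

**Correlation score.** Within one response group,
CS = −log10(P + 1e−20)·sign(Cor) for the Pearson correlation of each
(gene, event) pair over pairwise-complete observations (minimum 5).
The pseudocount caps |CS| at 20; constant vectors yield missing CS.

**Preranked GSEA.** Genes ranked by CS descending; the running sum gains
|CS|^w (normalized over hits, default weight w = 1) at hits and loses
1/(N − N_hit) at misses; ES is the deviation of largest magnitude. The
null permutes gene labels — with a per-event correlation ranking there is
no sample phenotype to permute — and the p-value is two-sided with the
add-one estimator. NES divides ES by the mean |null ES| of matching sign.
FDR is BH across pathways within one ranked list. Sets with fewer than 5
members after intersection with the universe are dropped. Defaults
(weight 1, 1000 permutations) are package choices; both are recorded in
output metadata.

**Screening.** pathAPAscore = 1 − 2p (ES > 0), 2p − 1 (ES < 0), 0 at
ES = 0 by continuity. Three sequential filters: |pathAPAscore| > 0.995
with FDR < 0.05 in at least one response group; opposite NES sign between
responders and non-responders; and survival of both filters in both
discovery cohorts with the same orientation (the sign of the responder
NES). Note that 0.995 requires p < 0.0025, so at least 400 permutations
are needed for any pair to pass; the default 1000 gives a p floor of
~0.001 (pathAPAscore ≈ 0.998).

**Survival selection.** Features are standardized for fitting (raw PDUI
is used at scoring time — the published formula multiplies raw PDUI).
Univariate Cox keeps features with p < 0.05; constant or non-converging
features are skipped with a warning. LASSO Cox fits an L1 path
(50 log-spaced penalties), scores each penalty by 5-fold cross-validated
Breslow partial likelihood, and applies the 1-SE rule, falling back to
the CV optimum if 1-SE zeroes everything. The Cox/LASSO stage runs on the
larger (GSE91061-like) cohort by default and is configurable.

**Scorer.** The canonical architecture is a single linear layer trained by
unpenalized logistic loss on the 70/30 stratified split of the pooled
(metaAPA) cohort — the published instance is linear, so the linear form is
authoritative and the shipped 10-term coefficients with intercept 0 are
the ground truth for `score()`. The optional `mlp` architecture adds one
identity-initialized ReLU hidden layer trained by full-batch gradient
descent and exports its equivalent linear form (exact while hidden
pre-activations remain non-negative; a warning reports any violation).

**Evaluation.** ROC/AUC against responder status; the optimal cutoff is
the Youden index on that ROC (the source states "optimal cutoff" without a
method); Kaplan–Meier curves for the high/low score groups with the
log-rank test; and a multivariate Cox fit of group membership plus any
supplied covariates for independence, reporting hazard ratios with 95%
CIs.

## Feature-based PPI module

Edges with STRING combined score ≤ 700 are dropped (strict inequality);
undirected duplicates keep the maximum score; self-loops are removed. The
largest connected component (size ties broken toward the lexicographically
smallest member) hosts a personalized PageRank: power iteration
x ← d·Px + (1 − d)·s with d = 0.85, teleport uniform over the seed genes
present in the component (seeds outside it are dropped with a warning),
L1 convergence tolerance 1e−10. Scores are a probability distribution and
match a dense solve of (I − dP)x = (1 − d)s to 1e−8 in the tests. The
top 200 genes by score form the module; seed genes are included and
flagged `is_seed` (whether the original module excluded its seeds is
unstated).

## Synthetic cohorts

The generator emulates the data model the analysis assumes, with ground
truth for every planted effect. PDUI is Beta-distributed with
concentration 20 (within-group spread ≈ 0.1, typical of bulk PDUI
estimates); cohort sizes default to 23 responders vs 82 non-responders,
and the two-cohort study generator uses 14/13 and 23/82. Planted
differential events shift the group means by ±`delta_effect` (default
0.2) around base means drawn from [0.3, 0.7] so the shift is never
clipped. Factor regulation couples log-normal factor expression to event
PDUI through a Gaussian copula whose latent correlation is back-solved
(2·sin(π·ρ_S/6)) so the realized Spearman correlation hits
`regulation_strength` (default 0.6); one factor is planted as a hub with
three times the targets of the others. Immune-coupled events load (0.8)
on a latent per-sample axis whose mean separates the response groups by
2.0; the member genes of each coupled pathway track the event latent with
per-gene loading 0.5 — flipped in sign between responders and
non-responders — implying within-pathway co-expression of 0.25, at the
upper end of realistic module coherence. Survival is exponential with
log-hazard = `survival_beta` (default −0.8, protective) times the
standardized latent axis, with independent exponential censoring
(~30%). Missingness is completely at random (default 5%). Randomness is
one hierarchical `SeedSequence` stream, split per output, so runs are
byte-reproducible and adding outputs never perturbs earlier draws.

What the generator does **not** emulate: batch effects, library-size or
GC biases, informative missingness (real DaPars2 coverage gaps track
expression), transcript-level structure beneath the gene-level events,
correlated clinical covariates, and single-cell count noise (T-cell
proportions are drawn directly from Dirichlet archetypes). Recovery
results on these cohorts therefore demonstrate correctness of the
machinery under the model's own assumptions, not performance on real
cohorts.

One behaviour worth knowing: because every immune-coupled event loads on
the same latent axis, their pathways cross-enrich each other's events —
and preranked GSEA with gene-label permutation is anti-conservative for
co-expressed gene blocks, so a few chance (null event, coupled pathway)
pairs survive even the cross-cohort screen. This mirrors the well-known
inter-gene-correlation inflation of preranked GSEA on real data.

## Problem sizes used in the test suite

Differential-APA recovery and null calibration run at the full default
scale (2000 events × 105 samples, B = 1000). The end-to-end scoring-system
recovery (ten seeded constructions, two cohorts each) runs on a reduced
cohort of 100 events × 250 genes × 12 pathways with the same group sizes,
thresholds and permutation counts — the construction is O(genes × events ×
permutations) through the per-event GSEA stage, and the reduced size keeps
the ten-seed experiment tractable while preserving every statistical
feature of the full configuration.

## Known limitations

* The permutation p floor (1/(B + 1)) couples the screening threshold to
  B; results at pathAPAscore > 0.995 are undefined below 400 permutations.
* `lasso_cox` cross-validates on the Breslow approximation; heavy tie
  structure in survival times would favour Efron.
* The MLP export is exact only while hidden pre-activations stay
  non-negative; with PDUI inputs in [0, 1] and identity initialization
  this holds in practice but is checked, not guaranteed.
* EPC and the GSEA null are Monte-Carlo; both record their sample counts
  and seeds in output metadata, and EPC ties among symmetric nodes are
  broken by sampling noise rather than exactly.
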