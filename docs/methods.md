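# Methods

## Sampling design and synthetic data

The package targets a balanced three-stand comparison: larch monoculture
(LF), birch (BF), and mixed larch–birch (MF), each with 7 plots and 2
composite soil samples per plot (42 samples). The synthetic generator
reproduces the statistical structure this design implies, so every
downstream stage is testable without field data.

**Soil properties.** Each of the eight indicators (SOC, TN, TP g/kg; AN
g/kg; AP mg/kg; pH; MWHC %; BD g/cm³) is drawn from a normal with its
stand's published mean and SD, truncated at zero by rejection resampling
(pH is untruncated; its range keeps it positive anyway). Only TP, at
roughly two SDs above zero, is meaningfully affected by truncation (a
small upward bias on the order of 2% of an SD). Indicators are drawn
independently by default because the source tabulation reports no
covariances; an optional exchangeable correlation (shared latent factor
per sample) exists solely to exercise the MDS correlation-screening
branch, and an optional plot-level random intercept (fraction of the
indicator SD, default 0) covers the otherwise-unmodelled 2-samples-per-plot
nesting.

**Communities.** Per domain, ASV i in sample s has latent log-abundance

    l_is = μ_i + σ·(√ρ·f_{b(i),s} + √(1−ρ)·ε_is) + log(1+δ)·1[i responsive to stand(s)]

with μ_i ~ N(0, τ²) (τ = 1.5) setting the rank-abundance spread, σ = 1
the per-sample variation, ρ the within-block latent correlation, and
counts drawn multinomially at depth 10 000 over softmax(l·s). The first
5 × 20 ASVs form correlated blocks (ρ = 0.9 by default) so co-occurrence
networks recover planted modules; a random 30% of ASVs is split evenly
across stands and up-shifted by δ in its stand's samples. Defaults are
400 bacterial and 200 fungal ASVs — scaled-down community sizes chosen so
the full pipeline (three stand networks plus a pooled one) runs in
seconds while keeping per-stand networks in the hundreds of nodes.

The fungal stand effect defaults to δ = 2.5, calibrated once so ANOSIM R
on generated fungal tables centres near 0.4 (observed mean ≈ 0.37, range
≈ 0.24–0.56 across seeds); the bacterial effect is 0, giving R ≈ 0. This
encodes the designed contrast: fungal composition tracks stand type,
bacterial composition does not.

**What the generator does not emulate:** phylogenetic signal, real
taxonomic composition, compositional negative correlations induced by a
few dominant taxa, sequencing-run batch effects, and any causal coupling
between the soil table and the communities. Consequently a passing
pipeline demonstrates statistical correctness and recovery of planted
structure — not that field data would show the same effect sizes; in
particular the SQI–microbe regressions are near-null on default synthetic
data because soil and communities are generated independently.

## Soil quality index

PCA is computed on the correlation matrix of standardized indicators
(units are incommensurate, and the communality-based weight definition
presumes standardized loadings); eigenvector signs are fixed so each PC's
largest-|loading| entry is positive. PCs with eigenvalue > 1.0 are
retained. "Top 10% of the highest loadings" is interpreted as the
norm-fraction band |loading| ≥ 0.9 × max|loading| within each retained PC
(standard minimum-data-set practice; a top-decile-count reading is the
other defensible option). Correlation screening is greedy: candidates are
visited in decreasing |loading| and dropped if Pearson-correlated at
|r| ≥ 0.7 with an already-kept candidate, which reduces to "keep the
highest-weight member" in the fully-correlated case. Varimax rotation is
not applied. Weights are communalities over the retained PCs
(Σ_k loading²_ik), normalized to sum to 1 over the MDS; the screening
trace records every retained PC, candidate set, and drop decision.

Scoring directions: SOC, TN, TP, AN, AP, MWHC, and pH default to "more is
better" (b = −2.5), BD to "less is better" (b = +2.5). Only BD is
uncontroversial; pH in the mildly acidic range studied (6.0–6.4) is
defensible either way and is overridable per analysis. The curve baseline
x₀ is the mean over the full scored dataset (all stands pooled), not
per-stand. x = 0 with b < 0 scores 0 by continuous extension and is
flagged. PCA uses all samples by default (plot means would also be
defensible; pooling preserves degrees of freedom for the 8-indicator PCA).

## Diversity and group statistics

Shannon uses natural log by default with a base flag (amplicon pipelines
differ; the choice is recorded in output metadata). Chao1 is the
bias-corrected form S_obs + F1(F1−1)/(2(F2+1)), defined when doubletons
are absent. No rarefaction is applied before diversity by default; the
generator's fixed depth makes it unnecessary, and a normalization policy
hook exists for real data. PCoA uses Gower double-centering; negative
eigenvalues (non-Euclidean Bray–Curtis) are reported but excluded from
coordinates and the percent-explained denominator. ANOSIM is rank-based
with average ties, R = (r̄_between − r̄_within)/(M/2), M = n(n−1)/2, and
permutation p = (1 + #{R* ≥ R})/(1 + n_perm), seeded. Tukey HSD letters
come from maximal cliques of the non-significance graph, lettered in
ascending group-mean order.

## Co-occurrence networks

Filters: occurrence strictly greater than 1/5 of samples and mean
relative abundance strictly greater than 0.01%. Edges: Spearman |r| > 0.7
with BH-adjusted q < 0.05 (the adjusted criterion is the stricter of the
two stated thresholds; a raw-p mode is available). Constant ASVs yield
undefined correlations and are excluded from edge calling with a warning.
Isolated nodes are dropped from the graph; the pre-drop candidate count
is retained. One network is built per stand type over the pooled
bacterial+fungal table, matching the per-stand topology comparison.

Topology panel: node/edge counts, % negative edges, density 2E/(N(N−1)),
average degree 2E/N, average clustering, and — on the largest connected
component, flagged when the graph is disconnected — diameter and average
path length. Modules come from Louvain maximization (resolution 1, fixed
seed for determinism; the community-detection algorithm is otherwise a
free choice).

Zi–Pi: Zi standardizes within-module degree against its module's mean and
population SD (SD = 0 gives Zi = 0, avoiding ±∞ on tiny modules); Pi =
1 − Σ_m (k_im/k_i)². Roles use thresholds Zi ≥ 2.5 and Pi ≥ 0.62; module
hubs, connectors, and network hubs are keystones.

Robustness: remove ⌊fraction·N⌋ nodes (uniform random, or module hubs
first ordered by Zi descending with ties broken by node id, topping up
randomly if hubs run out); a species "remains" iff it retains ≥ 1 edge,
and the proportion is relative to the original N. This makes robustness
at 50% removal at most 0.5 and exactly 0.5 on a complete graph.

Per-sample complexity: the subgraph induced on the network nodes present
in a sample is summarized by {average degree, density, clustering}
(configurable), each z-scored across samples (constant parameters score
0), and averaged. Samples with < 2 present nodes are flagged missing. For
the linkage stage the complexity comes from one pooled all-sample network
rather than per-stand networks — z-scoring within stand-specific networks
would remove exactly the between-stand variation the regression is meant
to use — and the keystone predictor uses the union of keystones over the
three stand networks.

## Linkage regressions

OLS of SQI on each predictor separately; diversity predictors are
z-scored with sample SD (n−1). R² equals the squared Pearson correlation;
the slope p is the usual t-test; 95% mean-response bands are available
for plotting. No multiple-testing correction is applied across the four
regressions (raw p's are reported); a flag exists. Degenerate predictors
(e.g. an empty keystone set) produce NaN rows rather than aborting the
report.

## Determinism and problem sizes

A single global seed fans out to stage seeds by fixed offsets, so any
stage re-run in isolation reproduces its in-pipeline output; pipeline
re-runs with the same config give identical file checksums. Replicated
property checks (SQI ordering, ANOSIM contrast) use 20 seeded replicates;
ANOSIM uses 999 permutations in the analysis scripts and 99 inside
replicate loops; robustness uses 100 replicates at 50% removal. These
sizes keep the full pipeline in the low seconds while leaving Monte-Carlo
error well inside the tested margins.

## Known limitations

Spearman on relative/multinomial counts does not correct for
compositionality (no SparCC/SPIEC-EASI-style adjustment); networks are
undirected snapshots; plot nesting is not modelled in the ANOVA or
regressions (a mixed-model extension is the natural next step); and MDS
selection near the eigenvalue-1.0 boundary is inherently unstable — an
indicator whose PC sits at the threshold may enter or leave the MDS
between replicates, which the screening trace makes visible.
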