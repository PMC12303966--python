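# standnet

Soil quality and microbial co-occurrence network analysis across forest
stand types.

## The problem

Mixing broadleaf species into conifer plantations changes litter inputs,
nutrient cycling, and the soil microbiome — but quantifying the effect on
*soil quality* requires compressing many physicochemical measurements into
one defensible number, and linking that number to microbial community
structure. This package implements the full analysis chain for a
three-stand-type comparison — larch monoculture (LF), birch (BF), and a
mixed larch–birch stand (MF), sampled as 7 plots × 2 composite samples per
stand (42 samples) — for ecologists who have a plot-level soil-property
table and paired bacterial/fungal ASV count tables (or who want to rehearse
the analysis on synthetic data with the same statistical structure).

## The method

**Soil quality index (SQI).** PCA on the correlation matrix of the eight
standardized indicators (SOC, TN, TP, AN, AP, pH, MWHC, BD) selects a
minimum data set (MDS): principal components with eigenvalue > 1.0 are
retained, candidates on each PC are the indicators within the top-10% band
of that PC's largest |loading|, and mutually correlated candidates
(|r| ≥ 0.7) are reduced to the highest-loading one. Each selected indicator
x is scored with the sigmoid

    SNL(x) = 1 / (1 + (x / x₀)^b)

where x₀ is the indicator's dataset mean and b = −2.5 ("more is better")
or +2.5 ("less is better", bulk density). The index is the communality-
weighted sum SQI = Σᵢ Wᵢ·SNLᵢ ∈ [0, 1].

**Community analysis.** Chao1 and Shannon alpha diversity; Bray–Curtis
dissimilarity with PCoA ordination; ANOSIM (R ∈ [−1, 1], permutation p);
one-way ANOVA with Tukey HSD compact letter displays.

**Co-occurrence networks.** Per stand type, the pooled bacteria+fungi
table is filtered (occurrence > 1/5 of samples, mean relative abundance
> 0.01%) and Spearman-correlated; edges require |r| > 0.7 and
Benjamini–Hochberg q < 0.05. The package reports the standard topology
panel, per-sample sub-network complexity (panel of z-scored subgraph
statistics), robustness (proportion of species retaining ≥ 1 edge after
removing 50% of nodes, randomly or module-hubs-first), and Zi–Pi node
roles: module hubs (Zi ≥ 2.5, Pi < 0.62), connectors (Zi < 2.5,
Pi ≥ 0.62) and network hubs (both) are keystone taxa.

**Linkage.** OLS regressions of SQI on z-scored bacterial diversity,
z-scored fungal diversity, network complexity, and keystone relative
abundance.

## Worked example

The numbered scripts under `analysis/` run the whole chain on synthetic
data (seed 1) and print their findings:

```sh
python analysis/01_simulate.py      # generate soil + ASV tables
python analysis/02_soil_quality.py  # MDS selection and SQI
python analysis/03_diversity.py     # alpha/beta diversity, ANOSIM
python analysis/04_networks.py      # per-stand networks, keystones
python analysis/05_linkage.py       # SQI ~ microbial predictors
```

`02_soil_quality.py` prints, for seed 1:

```
minimum data set: ['TN', 'AN', 'AP', 'MWHC', 'pH']
SQI by stand (mean +/- sd, Tukey letters):
        mean     sd   n letter
BF     0.551  0.033  14      b
LF     0.343  0.033  14      a
MF     0.560  0.048  14      b
ANOVA: F = 140.16, p = 1.6e-18
SQI increase vs LF: MF +63.32%, BF +60.71%
```

The mixed and birch stands share a Tukey letter and both exceed the larch
monoculture — the ordering the generator's published-parameter defaults
encode. `03_diversity.py` prints the designed beta-diversity contrast
(fungi ANOSIM R = 0.334, p = 0.001; bacteria R = 0.025, p = 0.246):
fungal community composition responds to stand type, bacterial does not.

The same pipeline runs from a single config via the CLI:

```sh
standnet all --seed 1 --out results/pipeline
standnet sqi results/data/soil_table.tsv --eig-min 1.0 --corr-cut 0.7
```

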