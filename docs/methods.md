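# Methods

This note documents the models behind `otoconv`: what each stage assumes,
the parameters that matter, what the synthetic generators do and do not
emulate, and the design choices made where the procedure was genuinely
open.

## The analysis problem

Ectopic Atoh1 expression converts cochlear supporting cells (SCs; Deiters'
and pillar cells) into hair-cell-like cells (cHCs) along a continuum of
transcriptional states SC1 → cHC1 → cHC2 → cHC3. The pipeline
characterizes that continuum from four data modalities: droplet
single-cell UMI counts, bulk RNA-seq of sorted cell populations
(duplicates of SC P26, cHC P33, OHC P7, OHC P22, IHC P74), single-cell
multiplex qPCR of a validated gene panel, and imaging-based counts of
reporter-positive and marker-double-positive cells.

## Synthetic data generators

All inputs can be simulated, which is how the test suite and the
acceptance script exercise the pipeline.

**UMI counts.** Counts are negative binomial with variance μ + μ²/θ
(gamma–Poisson mixture), the standard model for droplet UMI noise. Each
gene has a baseline log2 relative expression ~ N(1, 1); each population
carries 20 marker genes boosted by +3 log2 in that population only.
Cells of continuum populations draw a latent conversion coordinate
s ∈ [0, 1] uniformly from consecutive quarters of the unit interval
(SC1 lowest, cHC3 highest). Sixty conversion-program genes move with the
coordinate (±3 log2 across the full range, half rising and half falling);
mature hair cells (OHC/IHC) express the rising program at full level.
Program genes use θ = 8 versus θ = 2 for background genes — genes driven
by a shared regulatory state are less bursty, and this is what puts
pairwise correlations of program TFs into the R² > 0.25 regime a TF
co-expression analysis works in. Three special features exist: endogenous
*Atoh1* (3'UTR-counted) and the *Atoh1-HA* transgene, whose log2 means are
`5 + 3.4·s` plus N(0, 0.25) cell-level noise (θ = 50, appropriate for
highly expressed transcripts), and the *tdTomato* reporter expressed in
the SC-derived lineage. Library sizes are log-normal (μ = 8.5, σ = 0.35,
≈ 4,900 UMI median). Relative expressions are normalized to fractions per
cell, so a marker's *absolute* mean also depends on cell-wide composition —
as in real data. Per-cell library size is recorded in the metadata so
cell QC always refers to original sequencing depth regardless of later
gene subsetting.

The default preset is 7 populations × 100 cells with 1,000 genes — a
deliberately well-separated, desk-scale stand-in for a real cochlear
survey; the continuum preset is the 4 continuum populations × 150 cells.
What passing tests on these presets shows is that the *procedures* are
correct and calibrated, not that real cochlear data are this clean:
ambient RNA, doublets and cell-cycle heterogeneity are not simulated
(cycle-phase selection happens upstream of this pipeline; a label-based
metadata filter stands in).

**Bulk RNA-seq.** Five cell types × 2 duplicates over 2,000 genes (the
first 300 form the TF panel). Expression is block-structured: an SC
program, a pan-HC program partially engaged by cHCs, an immature-HC
program shared by cHC and OHC P7, a maturation program (OHC P22, weakly
IHC) and an IHC program, each ±3.2 log2 (≈ 9-fold — modest for genuine
cell-type markers). This geometry makes the cHC profile sit between SCs
and hair cells but closest to immature OHCs, the structure the distance
suite measures. Counts are NB (θ = 20) around
2^(group mean + N(0, 0.3)) per gene per replicate — the 0.3-log2
amplification noise emulates whole-transcriptome-amplification
variability — times a log-normal per-sample depth factor (σ = 0.15) that
gives TMM something to correct. `nb_dispersion = 0` switches all noise
off (counts = rounded means), used by tests. Gene lengths are log-normal
around 1.5 kb.

**Single-cell qPCR.** The assay panel (89 genes) is drawn from the bulk
truth — balanced over the three pairwise contrasts among SC/cHC/OHC, as a
DE-validated panel would be, plus two stable housekeeping-like genes — so
cross-platform comparisons have a shared ground truth. Per-assay
efficiency E ~ U(0.85, 1.05) and top-of-series Ct ~ U(8, 12). The
dilution series spans 15 threefold steps with Ct spacing
log2(3)/log2(1+E); the true LOD-Ct is the noiseless Ct of the most
dilute standard. Single cells follow
`Cq = LOD-Ct − log2(expr)/log2(1+E) + N(0, 0.1)` on a scale where
expr = 1 sits at the LOD; cells below the floor and a 2% random dropout
fraction do not amplify; 5% of chambers get a second melt peak
(primer-dimer artifact) and must be removed by QC. Per-gene-per-type
platform noise of 0.3 log2 decouples the two platforms realistically.
The 0.1-cycle Cq noise matches technical-replicate precision typical of
integrated-fluidic-circuit qPCR.

**Conversion counts.** Per sample, double-positive counts are binomial in
the number of reporter-positive cells at the condition's conversion rate;
an optional dislodged-cell fraction is counted and then excluded, as the
imaging quantification rule requires.

**Reproducibility.** Each artifact type (UMI, bulk, qPCR, counts) draws
from its own child stream of the master seed, so artifacts are
independently reproducible; the same seed yields byte-identical outputs.

## Preprocessing

Cells are filtered per sample to the [0.02, 0.98] quantile band of library
size (the band is a parameter; the quantile convention is linear
interpolation, end-points kept). Depth is then harmonized by drawing, for
each cell with total T_c and gene counts x_gc, new counts
Binomial(n = min_c T_c, p = x_gc/T_c) independently per gene. Zero counts
stay zero and every cell's expected total equals the reference depth;
because the binomials are independent, realized totals vary around it. An
optional multinomial mode (`downsample_multinomial`) makes totals exact
and is documented as a deviation from the per-gene formulation.
Blacklists (cell-cycle, apoptosis, ribosomal genes) are one-symbol-per-line
files matched case-insensitively.

HVG selection works on log2(count + 1): dispersion = variance/mean per
gene, 20 equal-frequency mean bins (undersized bins merge into their
neighbor), z-scoring of dispersion within bin, selection at z ≥ 1. Genes
with zero mean are never selected.

## Clustering

PCA (30 components by default) on gene-centered log2(count + 1); SNN
graph over the top PCs with k = 20 Euclidean nearest neighbors, Jaccard
weights over neighbor sets that include the cell itself, and pruning of
edges below 1/15 (a common default; weights are in [0, 1], symmetric, no
self-edges). Including the cell in its own neighbor set is what makes the
k = n−1 limit a complete graph of unit weights and keeps mutual-nearest
pairs connected at k = 1. Distance ties break toward the lower cell
index.

Community detection maximizes weighted modularity
Q = Σ_c [L_c/m − (d_c/2m)²]. Graphs with ≤ 8 nodes are solved exactly by
enumerating set partitions (the global optimum, deterministically);
larger graphs use Louvain with a seed-fixed node-visit order and ties in
modularity gain broken toward the lower community index, so results are
reproducible under a seed. The reported Q is always a direct formula
evaluation on the returned partition.

Markers are one-vs-rest two-sided Wilcoxon rank-sum tests on
log2(count + 1), reported when the log2 mean difference is ≥ 0.25 and the
gene is detected in ≥ 10% of in-cluster cells, with BH FDR across all
reported tests. t-SNE (seeded, PCA-initialized) is display-only.

## Pseudotime

Ordering genes require mean ≥ 0.1 and empirical dispersion
(variance/mean) ≥ 1.0 on expected counts after zeroing values below a
detection limit of 0.5. "Empirical dispersion" is taken as variance/mean,
the natural reading when no other definition is given.

The principal tree is k-means (25 centroids by default) in the PC space
of the ordering genes, joined by a minimum spanning tree; every cell is
projected onto the nearest point of its nearest edge. This
centroid–MST construction replaces the reversed-graph-embedding tree of
the original toolchain with a simpler, fully documented structure that
honors the same contract — a tree plus geodesic pseudotime — and is easy
to test. Pseudotime is geodesic distance along the tree from the root
centroid (the node nearest the mean position of the root cluster's
cells), scaled to [0, 1]. Branch labels are the tree-edge index a cell
projects to.

Pseudotime-dependent genes are found by a likelihood-ratio test of a
natural cubic spline (3 df, boundary knots at the τ range, interior knots
at quantiles) of log2(count + 1) on τ against an intercept-only model,
with a Gaussian working likelihood: the statistic n·ln(RSS₀/RSS₁) is
referred to χ²(3) and BH-adjusted. The Gaussian working model on
log-transformed counts is an approximation; at the preset's cell numbers
(hundreds) its type-I error is within [0.03, 0.07] at α = 0.05, which the
test suite checks. Branch-specific contrasts can be formed by adding the
branch label as a covariate. Binned profiles use 100 equal-width τ bins,
linear interpolation across empty bins and optional per-gene min-max
scaling.

The transgene analysis computes Pearson R² between log2(count + 1) of
Atoh1-HA and endogenous Atoh1 over cells expressing either feature, and
the linear-scale ratio of Atoh1-HA cluster means (cHC3/cHC1 by default).
On the default continuum preset these land in a strong-coupling regime
(R² ≈ 0.6, fold ≈ 2.4); the generator's loading and noise parameters
control where.

## TF network

Nodes are TF-list genes detected in ≥ 10 cells with log2(count + 1)
variance > 0.4 (the variance scale is taken as log-transformed counts,
the scale every other expression analysis here uses). All node pairs are
scored by Pearson correlation; an undirected edge exists iff r² > 0.25 —
read as a pure threshold with no p-value gate, matching the stated
edge rule; a p-value gate exists as an option, off by default. The sign
of r stays on the edge. Communities come from the same modularity engine
(on the unweighted edge set); hubs are the top-degree nodes per
community. The analysis is meant for the conversion-continuum cell
subset, exposed as a cell-filter argument.

## Bulk differential expression

TMM: the reference sample is the one whose upper-quartile CPM is closest
to the mean; per sample, M (log ratio) and A (log abundance) values over
genes positive in both libraries are doubly trimmed (30% on M, 5% on A,
rank-based) and averaged with inverse-asymptotic-variance weights;
factors are rescaled to geometric mean 1. "Trimming" of the count matrix
itself is read as low-expression filtering (CPM > 1 in ≥ 2 samples by
default), since no other definition is given.

DE re-implements the precision-weighted moderated-t route from its
published formulas: log2-CPM with a 0.5 prior count on TMM-effective
library sizes; a lowess trend of sqrt-residual-sd on average log2 count;
observation weights 1/trend⁴; weighted least squares per gene on cell-type
means; empirical-Bayes shrinkage of residual variances toward a prior
fitted by moments (scaled-F fit with a trigamma-inverse Newton solve);
moderated t on d + d₀ degrees of freedom; BH FDR within contrast. A plain
moderated t without trend weights is available (`use_weights=False`).
With two replicates per group the moderation is what makes the test
usable; the null simulation in the test suite verifies ≈ 0 false
discoveries at FDR 0.05 over 2,000 genes.

The "DE TF" set is the union of significant genes over the pairwise
contrasts among the named cell types intersected with the TF list
(union-of-pairwise rather than an F-test, which is exposed as the
default because pairwise contrasts are what the per-pair fold changes
feed); distances: Spearman distances are 1 − ρ between mean
TMM-normalized FPKM profiles, PC-space distances are Euclidean between
cell-type points in the PCA of log2(TMM-FPKM + 1) mean profiles on the
stated gene subset (all genes / TF panel / top-200 by MAD / ≥ 4-fold
genes), after removing genes with zero expression everywhere.

## qPCR quantification

Per assay, LOD-Ct = the highest Ct of the 15-point threefold dilution
series; the universal LOD-Ct is the median across assays (both modes are
exposed since either could anchor the conversion; per-assay is the
default). Efficiency = 10^(−1/slope) − 1 from the least-squares slope of
Ct on log10 relative concentration — base-10 regression regardless of the
threefold spacing, as is standard. Chambers with more than one melt peak
are removed before quantification. Expression is Log2(Ex) = LOD-Ct − Cq,
clipped at 0; a chamber present on the plate with no amplification is 0
(the LOD defines the floor), while a chamber *absent* after QC is NaN —
unknown, not undetected — and group statistics skip it. A per-assay
missingness report generalizes ad-hoc handling of assays with failed
chambers. Group comparisons run one-way ANOVA across cell types and,
when significant at 0.05, all pairwise t tests with Bonferroni correction
over the number of pairs. Cross-platform concordance correlates per-gene
log-ratios of group means between platforms (qPCR: Log2(Ex) differences;
bulk: log2 of mean FPKM + 0.5 ratios) and reports r² and the regression
line per cell-type pair.

## Classifier validation and conversion rates

The cluster-validation protocol: stratified 80/20 split per cluster;
min-max scaling and 30-component PCA (no whitening) fitted on the
training split only; RBF-SVM grid-searched over C ∈ {0.1, 1, 10, 100}
and γ ∈ {10⁻³ … 10} with 3-fold CV; accuracy read off the held-out
confusion matrix. The fitted transforms and split indices are exposed on
the report so the no-leakage property is externally checkable. The grids
are sensible defaults; the original protocol's were not specified.

Conversion rate = double-positive / reporter-positive per sample, with
dislodged endogenous cells excluded from numerator and denominator.
Conditions are compared on per-sample proportions (not pooled counts,
matching how such experiments are plotted and their n defined) with
two-sided Student's t, or a two-way ANOVA with interaction for factorial
(e.g. Atoh1 × Isl1) designs; a tissue-region factor can be added as an
explicit column when present.

## Numerical and degenerate-input conventions

Seeds: every stochastic routine takes an explicit seed; the pipeline
derives per-stage streams from a master seed and writes a manifest
(parameters + SHA-256 per output), so a run is reproducible from the
manifest alone. Degenerate inputs: empty graphs, emptied samples,
all-removed cells, missing gene lengths, reporter-free samples and
sub-fold CV clusters all raise informative errors rather than
propagating NaNs; constant genes yield p = 1 (not NaN) in the spline
test and are never selected as HVGs.

## Problem sizes

Defaults throughout are desk-scale choices the test suite runs end to
end: 700-cell surveys, 600-cell continua, 2,000-gene bulk studies with
duplicates, 89-assay plates with 68 cells, and 10–20 seed replications
for recovery statistics. They are the package's own study conditions;
all quantitative claims in the tests refer to them.

## Known limitations

* The principal tree is centroid-based: very unequal population sizes can
  starve a state of centroids; raise `n_centroids` accordingly.
* The spline LRT uses a Gaussian working likelihood on log counts; for
  very low-depth data a count-likelihood variant would be preferable.
* The Louvain stage above 8 nodes is a heuristic; only tiny graphs carry
  an optimality guarantee.
* TMM/voom/eBayes are re-implementations from the published formulas, not
  bindings to the reference R packages; factors agree with a direct
  evaluation of the trimmed-mean formula, but edge-case conventions
  (e.g. exact tie handling in trimming) may differ from other codebases.
* The synthetic generators are statistical stand-ins: they reproduce the
  noise families and effect structures the analyses assume, not the full
  biological complexity of cochlear tissue.
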