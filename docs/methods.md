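# Methods

This note records the models, defaults and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Marker discovery

Cells pass quality control when the number of detected features lies in
(2000, 10000), mitochondrial reads are below 5 % of the total, and total
molecules are below 100 000; the QC report carries the squared Pearson
correlation between per-cell feature and molecule counts and flags datasets
at or below 0.93, the level healthy singlet preparations exceed. On
generator-scale matrices (a few thousand genes rather than a genome-scale
panel) the feature floor scales down to 50
(`pipeline.synthetic_analysis_config`); all other constants keep their
defaults.

Normalization is ln(1 + 10⁴ · count / cell total). Composition equalization
finds, for each cell type present in every library, the smallest per-library
count and downsamples every library to it, uniformly without replacement
under a named seed. Cell types absent from any library are dropped with a
warning.

The one-vs-rest test is the two-sided Wilcoxon rank-sum on normalized
values: tie-corrected normal approximation without continuity correction,
switching to the exact null enumeration when both groups have ≤ 25
observations and the gene has no ties. Constant genes get p = 1. The fold
change is log2((mean_in + ε)/(mean_out + ε)) with ε = 10⁻⁹ (the base and
pseudocount are conventions; only the sign gates selection). "Percent
expressed" counts cells with a raw count above zero, computed after
equalization since ranking follows the DE step. Records passing the gates
(p < 0.01, positive fold change) are ranked within phase by Δpct
descending, ties broken by ascending p then lexicographic gene id; a gene
significant in several libraries goes to the phase with the largest Δpct so
phase lists are disjoint. Benjamini–Hochberg q-values are reported but
never used for selection, preserving the raw-gate behavior while keeping
the information.

A note on calibration: after exact composition balancing, genes whose
expression depends only on cell type are *balanced* across the compared
groups, which makes the unstratified rank-sum conservative for exactly
those genes — the intended effect of equalization (such genes should not
become markers). Genes without cell-type structure operate at the nominal
level.

## Bulk validation

TPM_gs = 10⁶ · (count_gs/length_g)/Σ_g(count_gs/length_g). Phase means are
taken over samples of the same ploidy class. Genes are dropped when their
maximum phase mean is below 1 TPM or their variance across phase means is
below the median (both config-exposed; the original filters are
qualitative). Remaining per-gene profiles are z-scored and clustered with
k-means, k = 8 by default — one cluster per direction-of-change × phase
combination — using 25 seeded starts and keeping the best inertia. Cluster
→ phase annotation is the centroid argmax (a codification of what was done
by eye in the source workflow). Concordance is the 3×3 contingency of
marker phase vs bulk peak phase over shared genes.

## Phase assignment and pseudotime positioning

The phase score is the standard expression-bin-matched module score: genes
detected in at least one cell are ranked by mean normalized expression and
split into 25 equal-occupancy bins; for each marker, 50 control genes are
drawn (seeded) from its bin; the score is the marker mean minus the control
mean per cell. Undetected genes take no part, which makes scores invariant
to padding the matrix with all-zero genes. Exact score ties are resolved in
the fixed order G1 < S < G2M and flagged.

Trajectory inference is out of scope; pseudotime is an input (the
generator's true cycle position θ serves in tests). Positioning aggregates
cell expression into 20 evenly spaced pseudotime bins (empty bins dropped
with a warning, ≥ 2 required), z-scores each gene's bin profile, k-means
them into 6 position clusters (both defaults config-exposed) and labels
clusters by centroid argmax bin; the per-gene peak bin is the profile
argmax. Constant genes cannot be standardized and land in a dedicated flat
cluster. Bin aggregation uses the mean.

## Time-lapse G1 dynamics

Frame classification: G1 if CFP exceeds its threshold, G2/M if YFP does,
otherwise S-or-early-G2 (the mCherry reporter persists into early G2, so S
and early G2 are one observable state). Both channels above threshold is
physically transient at the G2→M boundary; the frame goes to the larger
threshold-normalized excess and is flagged. Thresholds are config inputs
(the study used unstated detection cutoffs); `fluor.changepoint_threshold`
offers an automatic mode on a pooled channel distribution. A 3-frame
majority vote suppresses single-frame flicker (window 1 disables it).

Interval boundaries sit at inter-frame midpoints — unbiased under uniform
event timing within a frame, so reconstructed durations match truth within
one frame interval (10 min). The first/last run of a track is left-/right-
censored.

G1 durations use only intervals whose start (CDT1a appearance after
mitosis) was observed. Three metrics: (1) elapsed time to the movie end,
(2) the observed duration, imputing 20 h when censored — the known lower
bound on G1 in this root region — and (3) metric 1 as a fraction of the
movie. Survivorship fixes the risk set at the cells in G1 at t₀ (3 h post
ablation for ablated roots, movie start otherwise); cells entering G1 later
never join. The product-limit estimator and the two-group log-rank test are
computed with `lifelines`; tests verify both against hand tabulations.
Greenwood-based intervals are available from the fitter but are
reporting-only.

## Fluorescence quantification

CTCF = integrated density − area × mean background; negative values are
reported as-is. Per-cell-file scaling is min–max to [0, 1] (affine-
invariant; constant files map to 0.5 with a warning). Baseline-relative
series divide by the frame-zero value, dropping nuclei with non-positive
baselines. The change-point cutoff sorts the values and scans every split
exhaustively (prefix sums, O(n)) for the minimum total within-segment sum
of squares; the cutoff is the midpoint between the boundary values.

The anticorrelation test defaults to Spearman (robust to intensity
nonlinearity; the coefficient is configurable) and is one-sided toward
negative correlation since the hypothesis is directional; a two-sided flag
exists. Sampled permutations use the add-one convention
p = (1 + #{r* ≤ r})/(B + 1); for n ≤ 7 all n! permutations are enumerated
and p is the exact tail fraction. The 95 % CI is the percentile bootstrap
over cell indices.

## Synthetic-data generator

Counts are Gamma–Poisson (negative binomial, var = μ + 0.3 μ²) with
log-normal library-size factors (σ = 0.3). Cycle position θ ∈ [0,1) is
partitioned G1 [0, 0.55), S [0.55, 0.80), G2M [0.80, 1). Each phase gene
(60 per phase among 2000 by default) carries a uniform [3, 10] fold
amplitude inside its phase; baselines are log-normal (median ≈ 0.5 counts).
Cell-type genes (20 per type, 3 types, disjoint from phase and
mitochondrial genes) carry a ×5 multiplier in their type so composition
equalization has real work to do; mitochondrial baselines are tuned to a
2 % expected fraction. Enriched libraries place fraction π = 0.7 of cells
in the target phase, the rest following control occupancy; the control
library occupies phases proportional to mean duration (the ergodic
assumption). Purity is a free parameter — the enrichment levels of the real
libraries were shown only as images — so π is configurable rather than
calibrated.

Bulk samples scatter log-normally (σ = 0.2) around phase-mean expression ×
gene length, two independent sorts × three ploidy pools = six samples;
σ = 0 gives identical replicates for exact tests.

Tracks follow a semi-Markov G1→S→G2/M→division cycle with log-normal
durations (log-sd 0.5; means: control G1 20 h, ablated G1 2.5 h, S 3 h,
G2/M 3.5 h — G1 in this region outlasts a typical movie; ablated cells
pass through G1 in as little as ~2 h). The initial state approximates
stationarity (phase ∝ mean duration, uniform elapsed fraction) rather than
exact length-biased renewal sampling — adequate for the rate contrasts
tested, slightly biasing initial residual times short. In the ablated
regime movies start at ablation; cells in G1 then exit at a uniform time in
the 6 ± 1 h window and all subsequent G1 durations use the ablated
distribution. Channels emit 100 (on) vs 10 (off) plus Gaussian noise
(σ = 5): CFP on in G1, mCherry in S and the leading 40 % of G2/M (early
G2), YFP in the rest — so classification recovers truth exactly when noise
is small, and truth labels still separate S from G2/M for scoring. The
intensity assays emit phase-dependent CMAC means (G1 = 2 vs S = 1,
σ = 0.15), a ×1.4 multiplicative pulse at frame 2 for nuclei within 50 µm
of the wound, and bivariate probe signals with correlation ρ (default
−0.5).

What the generator does **not** emulate: doublets and ambient RNA, cell-
type-specific cycle speeds, spatial tissue geometry beyond a scalar wound
distance, segmentation/drift artifacts in tracks, and the S-phase
scarcity of the real ploidy sort (noted as an open asymmetry). Passing
tests therefore demonstrate that the *procedures* recover planted structure
under realistic noise, not that real data would behave as cleanly.

## Problem sizes and seeds

Default study-condition runs: 4 × 800 cells over 2000 genes for marker
discovery; 50 null seeds for gate calibration; 3000 fresh cells for
assignment; 75 tracks per arm, 15 h movies at 10-min frames for
survivorship. All randomness flows from one root seed through named
substreams (`config.substream`), so every stage is independently
reproducible and the CLI chain is byte-deterministic.

## Limitations

- Wilcoxon DE treats cells as exchangeable replicates; no pseudobulk or
  donor structure is modeled.
- The exact composition balance makes the DE gate conservative for genes
  with pure cell-type structure (see above) — a feature for marker
  selection, but the gate is then not a uniform-level test across all
  genes.
- The coordinated-exit window is modeled as uniform; the data show
  replicate-to-replicate spread of 1–2 h, which the window half-width
  represents but does not resolve per replicate.
- The G1-duration bin edges for short/medium/long summaries are
  configurable and deliberately not gated on, since the original binning is
  descriptive.
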