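# rootcycle

Tools for studying cell-cycle control in the *Arabidopsis thaliana* root —
from marker-gene discovery in phase-enriched single-cell RNA-seq, through
phase assignment of unlabeled cells, to the G1-exit dynamics of regenerating
cells in PlaCCI time-lapse movies.

## What it does

After root-tip ablation, cells just shootward of the wound re-enter the
cell cycle in a striking, coordinated way: cells that were sitting in G1
leave it almost simultaneously a few hours post ablation and then cycle with
drastically shortened G1 phases. Quantifying that behavior needs several
linked pieces of analysis, all implemented here:

1. **Marker discovery** (`rootcycle.markers`). Hydroxyurea synchronization
   yields libraries enriched for G1, S or G2/M. After quality control
   (features detected, mitochondrial fraction, total molecules) and seeded
   downsampling to equal cell-type composition, each gene is tested per
   enriched library against all other cells with a Wilcoxon rank-sum test
   (positive markers, p < 0.01). Markers are ranked by **percent
   differential expression** Δpct = pct_in − pct_out, the fraction of cells
   expressing the gene in its own library minus the fraction elsewhere, and
   the top 50 per phase are kept. A stricter filter (pct_in ≥ 0.80,
   log2 fold change > 0.25, top 5 by in-phase mean) yields in situ probe
   candidates.
2. **Bulk validation** (`rootcycle.bulk`). Ploidy-sorted bulk profiles
   (2n = G1, intermediate = S, 4n = G2/M) are TPM-normalized, averaged per
   phase, filtered, z-scored and clustered with k-means (k = 8); each
   cluster's peak phase is compared with the single-cell marker phases.
3. **Phase assignment** (`rootcycle.phase`). Cells are scored per phase with
   expression-bin-matched module scores (marker mean minus size-matched
   control-gene mean); the call is the argmax. Genes can also be positioned
   along a supplied cell-cycle pseudotime by bin-aggregate-cluster.
4. **Time-lapse G1 dynamics** (`rootcycle.timelapse`). PlaCCI three-channel
   nucleus tracks (CDT1a-CFP → G1, HTR13-mCherry → S/early G2,
   CYCB1;1-YFP → late G2/M) are classified frame-by-frame by threshold,
   turned into censoring-aware phase intervals, and summarized as three
   G1-duration metrics (elapsed-to-movie-end, 20 h imputation, movie
   fraction). G1-exit survivorship of the population in G1 at time zero is
   estimated with the Kaplan–Meier product-limit estimator
   S(t) = Π_{t_i ≤ t} (1 − d_i/n_i) and arms are compared with the
   log-rank test, χ² = (Σ(O−E))²/ΣV.
5. **Fluorescence quantification** (`rootcycle.fluor`). CTCF = integrated
   density − area × mean background; per-cell-file min-max scaling;
   baseline-relative time series; change-point signal/background cutoffs
   (exact single-split least squares); and a one-sided permutation test for
   probe anticorrelation with a bootstrap percentile CI (exact enumeration
   for n ≤ 7).
6. **Synthetic data** (`rootcycle.simulate`). A fully parameterized
   generator reproduces the statistical structure of all of the above —
   negative-binomial phase-structured counts, enriched libraries of
   configurable purity, ploidy bulk means, semi-Markov PlaCCI tracks with a
   coordinated-exit ablation regime, and the fluorescence assays — with
   ground truth retained, so every stage can be scored by parameter
   recovery.

## Worked example

```
python analysis/01_simulate.py
python analysis/02_markers.py
python analysis/05_timelapse_survival.py
```

prints (seed 1):

```
G1: 50 markers, 100.0% planted in phase
S: 50 markers, 100.0% planted in phase
G2M: 50 markers, 100.0% planted in phase
ablated: 85 G1 entries, 25% right-censored, median elapsed 2.0 h
control: 56 G1 entries, 96% right-censored, median elapsed 6.5 h
log-rank chi2 = 58.7, p = 1.84e-14; median G1 residence control 7.2 h vs ablated 3.1 h
```

Every top-50 marker list is recovered from the planted truth; control G1
phases mostly outlast the 15 h movie (96 % right-censored) while ablated
cells exit G1 coordinately ~6 h post ablation and then cycle with ~2 h G1
phases, giving a decisively significant survivorship separation. The
remaining drivers (`03`, `04`, `06`) validate markers against bulk, score
phase-assignment accuracy, and run the fluorescence suite; all outputs land
under `results/`.

The same stages are available as a CLI:

```
rootcycle simulate --seed 1 --out results/data
rootcycle markers --counts results/data/counts --meta results/data/meta.tsv \
    --config results/data/config.yaml --out results/markers
```

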