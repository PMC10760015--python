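"""Validation of single-cell phase markers against ploidy-sorted bulk profiles.

Bulk samples sorted by ploidy proxy the cycle phases (2n = G1, intermediate =
S, 4n = G2/M). Counts are TPM-normalized, averaged per phase, filtered for
expression and variance, z-scored and clustered with k-means (k = 8 by
default, one cluster per direction-of-change x phase combination); each
cluster is annotated with the phase where its centroid peaks, and marker
phase labels are compared with bulk peak phases in a 3x3 contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import PHASES
from .markers import MarkerSet


@dataclass
class BulkTable:
    """Raw gene x sample counts with gene lengths and a sample -> phase map."""

    counts: pd.DataFrame           # genes x samples, integer
    gene_lengths: pd.Series        # bp, indexed by gene
    sample_phase: pd.Series        # phase label, indexed by sample

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.gene_lengths.index):
            raise ValueError("gene_lengths index must match counts rows")
        if set(self.counts.columns) != set(self.sample_phase.index):
            raise ValueError("sample_phase must cover exactly the count columns")
        if (self.gene_lengths <= 0).any():
            bad = self.gene_lengths.index[self.gene_lengths <= 0][0]
            raise ValueError(f"non-positive gene length for {bad!r}")
        present = set(self.sample_phase)
        missing = set(PHASES) - present
        if missing:
            raise ValueError(f"phases without samples: {sorted(missing)}")


@dataclass
class PhasePatternClusters:
    """k-means clusters of standardized per-phase mean profiles."""

    assignment: pd.Series          # gene -> cluster id
    centroids: pd.DataFrame        # cluster x phase (z-scored space)
    peak_phase: pd.Series          # cluster -> phase of centroid argmax

    def gene_peak_phase(self) -> pd.Series:
        return self.assignment.map(self.peak_phase)


def write_bulk_table(b: BulkTable, prefix) -> None:
    """Write counts / gene lengths / sample-phase map as sibling TSVs."""
    from pathlib import Path
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    b.counts.rename_axis("gene_id").to_csv(f"{prefix}_counts.tsv", sep="\t")
    b.gene_lengths.rename("length_bp").rename_axis("gene_id") \
        .to_csv(f"{prefix}_lengths.tsv", sep="\t")
    b.sample_phase.rename("phase").rename_axis("sample") \
        .to_csv(f"{prefix}_phases.tsv", sep="\t")


def read_bulk_table(prefix) -> BulkTable:
    counts = pd.read_csv(f"{prefix}_counts.tsv", sep="\t", index_col=0)
    lengths = pd.read_csv(f"{prefix}_lengths.tsv", sep="\t", index_col=0)["length_bp"]
    phases = pd.read_csv(f"{prefix}_phases.tsv", sep="\t", index_col=0)["phase"]
    return BulkTable(counts=counts, gene_lengths=lengths, sample_phase=phases)


def tpm_normalize(b: BulkTable) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates scaled to 1e6 per sample."""
    rate = b.counts.div(b.gene_lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero total counts")
    return rate.div(totals, axis=1) * 1e6


def phase_means(tpm: pd.DataFrame, sample_phase: pd.Series) -> pd.DataFrame:
    """Mean TPM per phase, columns ordered G1, S, G2M."""
    means = tpm.T.groupby(sample_phase).mean().T
    return means[list(PHASES)]


def filter_and_cluster(
    tpm: pd.DataFrame, b: BulkTable, k: int = 8, seed: int = 0,
    min_tpm: float = 1.0, var_quantile: float = 0.5, n_starts: int = 25,
) -> PhasePatternClusters:
    """Filter low-expression/low-variance genes and k-means the phase profiles.

    Genes whose maximum phase-mean TPM is below ``min_tpm`` or whose variance
    across phase means falls below the ``var_quantile`` quantile are dropped;
    remaining profiles are z-scored per gene and clustered with seeded
    multi-start k-means (best inertia of ``n_starts`` runs).
    """
    means = phase_means(tpm, b.sample_phase)
    expressed = means.max(axis=1) >= min_tpm
    var = means.var(axis=1, ddof=0)
    var_gate = (var >= var[expressed].quantile(var_quantile)) & (var > 0)
    kept = means[expressed & var_gate]
    if len(kept) < k:
        raise ValueError(f"only {len(kept)} genes survive the filters; need >= k = {k}")
    z = kept.sub(kept.mean(axis=1), axis=0).div(kept.std(axis=1, ddof=0), axis=0)
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
    labels = km.fit_predict(z.to_numpy())
    centroids = pd.DataFrame(km.cluster_centers_, columns=list(PHASES))
    peak = pd.Series([PHASES[i] for i in centroids.to_numpy().argmax(axis=1)],
                     index=centroids.index)
    return PhasePatternClusters(
        assignment=pd.Series(labels, index=kept.index, name="cluster"),
        centroids=centroids, peak_phase=peak,
    )


def concordance(ms: MarkerSet, clusters: PhasePatternClusters) -> dict:
    """Agreement between single-cell marker phases and bulk peak phases.

    Returns the 3x3 contingency table over shared genes, per-phase agreement
    fractions, and the fraction of markers absent from the clustered set.
    """
    bulk_phase = clusters.gene_peak_phase()
    marker_phase = {g: p for p in PHASES for g in ms.per_phase.get(p, [])}
    shared = [g for g in marker_phase if g in bulk_phase.index]
    if not shared:
        raise ValueError("no overlap between marker genes and clustered bulk genes")
    table = pd.DataFrame(0, index=list(PHASES), columns=list(PHASES))
    for g in shared:
        table.loc[marker_phase[g], bulk_phase[g]] += 1
    agreement = {}
    for p in PHASES:
        n = int(table.loc[p].sum())
        agreement[p] = float(table.loc[p, p] / n) if n else float("nan")
    n_markers = len(marker_phase)
    return {
        "table": table,
        "agreement": agreement,
        "fraction_markers_missing": 1.0 - len(shared) / n_markers if n_markers else 0.0,
        "n_shared": len(shared),
    }
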