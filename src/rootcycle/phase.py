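"""Phase assignment by marker module scores, and pseudotime positioning.

A cell's score for a phase is the mean normalized expression of that phase's
markers minus the mean of a size-matched control gene set drawn from the same
average-expression bins, so library depth and general expression level cancel;
the call is the argmax score. Genes are positioned along a supplied cell-cycle
pseudotime by averaging expression in evenly spaced bins and clustering the
standardized bin profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import PHASES
from .markers import MarkerSet

FLAT_CLUSTER = -1  # genes constant over pseudotime


def score_cells_by_phase(
    norm: np.ndarray, gene_ids: np.ndarray, cell_ids: np.ndarray,
    ms: MarkerSet, seed: int, n_bins: int = 25, ctrl_size: int = 50,
) -> pd.DataFrame:
    """Module scores per phase and the argmax phase call for every cell.

    Control genes are drawn (seeded, per marker) from the expression bin of
    that marker, among genes detected in at least one cell; genes never
    expressed take no part in binning, so padding the matrix with all-zero
    genes leaves scores unchanged. Exact ties are resolved in the fixed order
    G1 < S < G2M and flagged.
    """
    gene_index = pd.Index(gene_ids)
    avg = norm.mean(axis=1)
    expressed = avg > 0
    if expressed.sum() < n_bins:
        raise ValueError("too few expressed genes to build expression bins")
    # quantile bins over expressed genes only
    ranks = pd.Series(avg[expressed]).rank(method="first")
    bin_of_expressed = np.ceil(ranks / (len(ranks) / n_bins)).astype(int).clip(1, n_bins)
    bin_of = pd.Series(0, index=np.arange(len(gene_ids)))
    bin_of[np.flatnonzero(expressed)] = bin_of_expressed.to_numpy()

    rng = np.random.default_rng(seed)
    scores = {}
    for phase in PHASES:
        markers = ms.per_phase.get(phase, [])
        rows = gene_index.get_indexer([m for m in markers if m in gene_index])
        rows = rows[rows >= 0]
        if len(rows) == 0:
            raise ValueError(f"no detectable markers for phase {phase}")
        ctrl: set[int] = set()
        for r in rows:
            pool = np.flatnonzero((bin_of.to_numpy() == bin_of.iloc[r]) & expressed)
            take = min(ctrl_size, len(pool))
            ctrl.update(rng.choice(pool, size=take, replace=False))
        ctrl_rows = np.array(sorted(ctrl))
        scores[phase] = norm[rows].mean(axis=0) - norm[ctrl_rows].mean(axis=0)

    score_mat = np.column_stack([scores[p] for p in PHASES])
    best = score_mat.argmax(axis=1)  # argmax takes the first max: G1 < S < G2M
    ties = (score_mat == score_mat.max(axis=1, keepdims=True)).sum(axis=1) > 1
    return pd.DataFrame({
        "cell_id": cell_ids,
        "score_G1": score_mat[:, 0], "score_S": score_mat[:, 1],
        "score_G2M": score_mat[:, 2],
        "assigned_phase": np.array(PHASES, dtype=object)[best],
        "tie_flag": ties,
    })


@dataclass
class PseudotimePositioning:
    """Bin-aggregated expression and gene position clusters along pseudotime."""

    bin_edges: np.ndarray          # length n_bins + 1, even spacing
    aggregate: pd.DataFrame        # non-empty bin centers x genes (mean expression)
    gene_cluster: pd.Series        # gene -> cluster id (FLAT_CLUSTER if constant)
    cluster_peak_bin: pd.Series    # cluster -> index of centroid argmax bin

    def gene_peak_bin(self) -> pd.Series:
        """Peak bin per gene: its own profile argmax (flat genes get -1)."""
        peaks = self.aggregate.to_numpy().argmax(axis=0)
        out = pd.Series(peaks, index=self.aggregate.columns)
        out[self.gene_cluster == FLAT_CLUSTER] = -1
        return out


def position_genes_on_pseudotime(
    norm: np.ndarray, gene_ids: np.ndarray, pseudotime: np.ndarray,
    genes: list[str], n_bins: int = 20, n_clusters: int = 6, seed: int = 0,
) -> PseudotimePositioning:
    """Aggregate expression in evenly spaced pseudotime bins and cluster genes.

    Bin means (cells per bin averaged) form one profile per gene; profiles are
    z-scored and clustered with seeded k-means, each cluster labeled by the
    bin where its centroid peaks. Genes constant across bins cannot be
    standardized and land in a dedicated flat cluster.
    """
    pseudotime = np.asarray(pseudotime, dtype=float)
    if not np.all(np.isfinite(pseudotime)):
        raise ValueError("pseudotime must be finite for every cell")
    gene_index = pd.Index(gene_ids)
    rows = gene_index.get_indexer(genes)
    if (rows < 0).any():
        missing = [g for g, r in zip(genes, rows) if r < 0]
        raise ValueError(f"genes absent from the matrix: {missing[:5]}")
    edges = np.linspace(pseudotime.min(), pseudotime.max(), n_bins + 1)
    which = np.clip(np.digitize(pseudotime, edges[1:-1]), 0, n_bins - 1)
    profiles, centers = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        profiles.append(norm[np.ix_(rows, np.flatnonzero(mask))].mean(axis=1))
        centers.append(0.5 * (edges[b] + edges[b + 1]))
    if len(profiles) < 2:
        raise ValueError("fewer than 2 non-empty pseudotime bins")
    if len(profiles) < n_bins:
        warnings.warn(f"{n_bins - len(profiles)} empty pseudotime bins dropped",
                      stacklevel=2)
    agg = pd.DataFrame(np.column_stack(profiles).T, index=centers, columns=genes)

    sd = agg.std(axis=0, ddof=0)
    flat = sd == 0
    cluster = pd.Series(FLAT_CLUSTER, index=genes, dtype=int)
    varying = agg.loc[:, ~flat]
    z = varying.sub(varying.mean(axis=0), axis=1).div(sd[~flat], axis=1)
    k = min(n_clusters, z.shape[1])
    if k >= 1 and z.shape[1] >= 1:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(z.T.to_numpy())
        cluster[~flat] = labels
        peak = pd.Series(km.cluster_centers_.argmax(axis=1), index=range(k))
    else:
        peak = pd.Series(dtype=int)
    return PseudotimePositioning(bin_edges=edges, aggregate=agg,
                                 gene_cluster=cluster, cluster_peak_bin=peak)
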