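"""Cell-cycle phase marker discovery from phase-enriched libraries.

The procedure: filter cells on detected features, mitochondrial fraction and
total molecules; log-normalize; equalize cell-type composition across
libraries by seeded downsampling to the smallest stratum; test each gene in
each phase-enriched library against all other cells with a Wilcoxon rank-sum
test, keeping positive markers below the p cutoff; rank markers by percent
differential expression (delta_pct, the fraction of cells expressing the gene
in its own library minus the fraction expressing it elsewhere) and keep the
top N per phase. A stricter filter (pct_in >= 0.80, LFC > 0.25, top 5 by
in-phase mean expression) yields in situ probe candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .io import CountMatrix, PHASES

ENRICHED = {"G1_enriched": "G1", "S_enriched": "S", "G2M_enriched": "G2M"}


# ---------------------------------------------------------------------------
# quality control and normalization
# ---------------------------------------------------------------------------

def filter_cells_qc(
    m: CountMatrix, meta: pd.DataFrame, cfg: AnalysisConfig,
    mito_gene_ids: set[str] | None = None,
) -> tuple[CountMatrix, pd.DataFrame, dict]:
    """Keep cells passing the feature-count, mitochondrial and total gates.

    The report carries per-gate attrition and the squared Pearson correlation
    between per-cell feature counts and total counts, flagged when it does not
    exceed ``cfg.min_r_squared`` (healthy singlet datasets exceed 0.93).
    """
    if mito_gene_ids is None:
        mito_gene_ids = {g for g in m.gene_ids if str(g).startswith("MT-")}
    counts = m.counts
    features = np.asarray((counts > 0).sum(axis=0)).ravel()
    totals = np.asarray(counts.sum(axis=0)).ravel()
    mito_mask = np.isin(m.gene_ids, list(mito_gene_ids))
    mito = np.asarray(counts[mito_mask].sum(axis=0)).ravel() if mito_mask.any() \
        else np.zeros(m.n_cells)
    mito_pct = np.divide(100.0 * mito, totals, out=np.zeros(m.n_cells),
                         where=totals > 0)

    gate_features = (features > cfg.min_features) & (features < cfg.max_features)
    gate_mito = mito_pct < cfg.max_mito_pct
    gate_total = totals < cfg.max_counts
    keep = gate_features & gate_mito & gate_total
    report = {
        "n_input": m.n_cells,
        "n_kept": int(keep.sum()),
        "failed_features": int((~gate_features).sum()),
        "failed_mito": int((~gate_mito).sum()),
        "failed_total": int((~gate_total).sum()),
    }
    if not keep.any():
        raise ValueError(f"quality control removed every cell: {report}")
    f, t = features[keep].astype(float), totals[keep].astype(float)
    if np.std(f) == 0 or np.std(t) == 0:
        r2 = float("nan")
    else:
        r2 = float(np.corrcoef(f, t)[0, 1] ** 2)
    report["r_squared"] = r2
    report["r_squared_flag"] = bool(not (r2 > cfg.min_r_squared))
    kept = CountMatrix(counts[:, keep], m.gene_ids, m.cell_ids[keep])
    meta_kept = meta[meta["cell_id"].isin(kept.cell_ids)].reset_index(drop=True)
    return kept, meta_kept, report


def lognormalize(m: CountMatrix, scale: float = 10_000.0) -> np.ndarray:
    """ln(1 + scale * count / cell total), dense genes x cells.

    Scale-invariant per cell (doubling a cell's counts changes nothing) and
    monotone in counts within a cell; zeros map to zero.
    """
    totals = np.asarray(m.counts.sum(axis=0)).ravel().astype(float)
    if (totals == 0).any():
        bad = m.cell_ids[totals == 0][0]
        raise ValueError(f"cell {bad!r} has zero total counts (run QC first)")
    x = m.counts.toarray().astype(float)
    return np.log1p(scale * x / totals[None, :])


def equalize_composition(meta: pd.DataFrame, seed: int) -> np.ndarray:
    """Downsample so every library contributes equally to each cell type.

    For each cell type present in every library, each library is sampled
    uniformly without replacement down to the smallest per-library count of
    that type. Cell types missing from any library are dropped with a warning.
    Returns the retained cell ids.
    """
    rng = np.random.default_rng(seed)
    libs = sorted(meta["library"].unique())
    kept: list[str] = []
    for ct, grp in meta.groupby("cell_type", sort=True):
        per_lib = grp.groupby("library")["cell_id"].count()
        if set(per_lib.index) != set(libs):
            warnings.warn(f"cell type {ct!r} absent from some libraries; dropped",
                          stacklevel=2)
            continue
        n = int(per_lib.min())
        for lib in libs:
            ids = np.sort(grp.loc[grp["library"] == lib, "cell_id"].to_numpy())
            kept.extend(rng.choice(ids, size=n, replace=False))
    return np.array(sorted(kept), dtype=object)


# ---------------------------------------------------------------------------
# differential expression and ranking
# ---------------------------------------------------------------------------

def _ranksum_pvalues(x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum per gene (rows).

    Uses the tie-corrected normal approximation; when both groups have at most
    25 observations and a gene has no ties, the exact null enumeration is used
    instead. Constant genes get p = 1 by convention.
    """
    n_in, n_out = x_in.shape[1], x_out.shape[1]
    small = max(n_in, n_out) <= 25
    if small:
        p = np.ones(x_in.shape[0])
        for i in range(x_in.shape[0]):
            combined = np.concatenate([x_in[i], x_out[i]])
            if np.ptp(combined) == 0:
                continue
            method = "exact" if len(np.unique(combined)) == len(combined) else "asymptotic"
            p[i] = stats.mannwhitneyu(x_in[i], x_out[i],
                                      alternative="two-sided", method=method).pvalue
        return p
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.mannwhitneyu(x_in, x_out, alternative="two-sided",
                                 method="asymptotic", use_continuity=False,
                                 axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    constant = np.ptp(np.hstack([x_in, x_out]), axis=1) == 0
    p[constant | ~np.isfinite(p)] = 1.0
    return p


def de_one_vs_rest(
    norm: np.ndarray, gene_ids: np.ndarray, meta: pd.DataFrame,
    cfg: AnalysisConfig, return_all: bool = False,
) -> pd.DataFrame:
    """One-vs-rest marker records for each phase-enriched library.

    For every gene and every enriched library: rank-sum p-value of that
    library's cells against all other cells on normalized values; log2 fold
    change of means with a small pseudocount; fractions of expressing cells
    inside and outside the library. Records are gated on positive fold change
    and p below the cutoff unless ``return_all``. Benjamini-Hochberg q-values
    are reported alongside but never used for selection.
    """
    if norm.shape[1] != len(meta):
        raise ValueError("normalized matrix columns must match metadata rows")
    libs_per_cell = meta["library"].to_numpy()
    records = []
    eps = cfg.lfc_pseudocount
    for lib_name, phase in ENRICHED.items():
        in_mask = libs_per_cell == lib_name
        if in_mask.sum() < 3 or (~in_mask).sum() < 3:
            raise ValueError(f"library {lib_name} needs >= 3 cells in and out")
        x_in, x_out = norm[:, in_mask], norm[:, ~in_mask]
        p = _ranksum_pvalues(x_in, x_out)
        mean_in, mean_out = x_in.mean(axis=1), x_out.mean(axis=1)
        lfc = np.log2((mean_in + eps) / (mean_out + eps))
        pct_in = (x_in > 0).mean(axis=1)
        pct_out = (x_out > 0).mean(axis=1)
        records.append(pd.DataFrame({
            "gene_id": gene_ids, "phase": phase, "p_value": p, "lfc": lfc,
            "pct_in": pct_in, "pct_out": pct_out,
            "delta_pct": pct_in - pct_out, "mean_in": mean_in,
        }))
    table = pd.concat(records, ignore_index=True)
    table["q_value"] = _bh_qvalues(table["p_value"].to_numpy())
    table["significant"] = (table["p_value"] < cfg.de_p_cutoff) & \
        ((table["lfc"] > 0) if cfg.positive_only else True)
    if return_all:
        return table
    return table[table["significant"]].reset_index(drop=True)


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


@dataclass
class MarkerSet:
    """Ordered top-N marker genes per phase; phase lists are disjoint."""

    per_phase: dict[str, list[str]]
    records: pd.DataFrame

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for phase, genes in self.per_phase.items():
            overlap = seen & set(genes)
            if overlap:
                raise ValueError(f"marker lists overlap across phases: {sorted(overlap)}")
            seen |= set(genes)

    def all_genes(self) -> list[str]:
        return [g for p in PHASES for g in self.per_phase.get(p, [])]


def select_markers(records: pd.DataFrame, top_n: int = 50) -> MarkerSet:
    """Rank gated records by delta_pct and keep the top N per phase.

    A gene significant in several libraries is assigned to the phase where its
    delta_pct is largest, so the phase lists are disjoint. Ties are broken by
    ascending p-value, then lexicographic gene id. Input row order is
    irrelevant.
    """
    if records.empty:
        raise ValueError("no marker records passed the gates")
    rec = records.sort_values(
        ["gene_id", "delta_pct", "p_value"],
        ascending=[True, False, True], kind="stable",
    ).drop_duplicates("gene_id", keep="first")
    rec = rec.sort_values(
        ["phase", "delta_pct", "p_value", "gene_id"],
        ascending=[True, False, True, True], kind="stable",
    )
    per_phase: dict[str, list[str]] = {}
    frames = []
    for phase in PHASES:
        sub = rec[rec["phase"] == phase].head(top_n).copy()
        if len(sub) < top_n:
            warnings.warn(f"only {len(sub)} markers survive for phase {phase}",
                          stacklevel=2)
        sub["rank"] = np.arange(1, len(sub) + 1)
        per_phase[phase] = sub["gene_id"].tolist()
        frames.append(sub)
    return MarkerSet(per_phase=per_phase, records=pd.concat(frames, ignore_index=True))


def marker_set_from_table(records: pd.DataFrame) -> MarkerSet:
    """Rebuild a MarkerSet from its written TSV (phase / gene_id / rank)."""
    per_phase = {
        p: records[records["phase"] == p].sort_values("rank")["gene_id"].tolist()
        for p in PHASES if (records["phase"] == p).any()
    }
    return MarkerSet(per_phase=per_phase, records=records)


def select_probe_candidates(
    records: pd.DataFrame, cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """In situ probe candidates: strongly, broadly expressed phase markers.

    Keeps records expressed in at least 80 percent of in-phase cells with a
    log fold change strictly above 0.25, then returns the 5 most highly
    expressed (mean in-phase normalized expression) per phase.
    """
    cfg = cfg or AnalysisConfig()
    ok = records[(records["pct_in"] >= cfg.probe_min_pct) &
                 (records["lfc"] > cfg.probe_min_lfc)]
    if ok.empty:
        warnings.warn("no probe candidates pass the filters", stacklevel=2)
        return ok.copy()
    out = (ok.sort_values(["phase", "mean_in", "gene_id"],
                          ascending=[True, False, True], kind="stable")
             .groupby("phase", sort=True).head(cfg.probe_top_n)
             .reset_index(drop=True))
    return out.rename(columns={"mean_in": "mean_in_phase"})
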