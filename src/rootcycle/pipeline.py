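"""End-to-end stage drivers chaining the module operations.

These are the functions the numbered analysis scripts, the CLI and the
acceptance checks call; each takes explicit configs and returns plain
dictionaries of results so no stage hides state from its caller.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bulk as bulk_mod
from . import markers as mk
from . import phase as ph
from . import simulate as sim
from . import timelapse as tl
from .config import AnalysisConfig
from .io import PHASES, CountMatrix


def synthetic_analysis_config(seed: int, **overrides) -> AnalysisConfig:
    """Analysis constants adapted to generator-scale matrices.

    The study's feature-count floor (2000) assumes genome-scale panels; on a
    few-thousand-gene synthetic matrix the floor scales down to 50 detected
    genes while every other constant keeps its stated default.
    """
    overrides.setdefault("min_features", 50)
    return AnalysisConfig(seed=seed, **overrides)


def discover_markers(
    cm: CountMatrix, meta: pd.DataFrame, cfg: AnalysisConfig,
) -> dict:
    """QC -> log-normalize -> equalize composition -> DE -> top-N markers."""
    cm_qc, meta_qc, qc_report = mk.filter_cells_qc(cm, meta, cfg)
    keep_ids = mk.equalize_composition(meta_qc, seed=cfg.seed)
    keep_mask = np.isin(cm_qc.cell_ids, keep_ids)
    cm_eq = CountMatrix(cm_qc.counts[:, keep_mask], cm_qc.gene_ids,
                        cm_qc.cell_ids[keep_mask])
    meta_eq = meta_qc[meta_qc["cell_id"].isin(keep_ids)].reset_index(drop=True)
    norm = mk.lognormalize(cm_eq)
    records = mk.de_one_vs_rest(norm, cm_eq.gene_ids, meta_eq, cfg)
    marker_set = mk.select_markers(records, top_n=cfg.top_n_markers)
    probes = mk.select_probe_candidates(records, cfg)
    return {
        "qc_report": qc_report, "counts": cm_eq, "meta": meta_eq,
        "norm": norm, "records": records, "marker_set": marker_set,
        "probe_candidates": probes,
    }


def marker_recovery(marker_set: mk.MarkerSet, program: pd.DataFrame) -> dict[str, float]:
    """Fraction of each phase's selected markers planted in that phase."""
    truth = program.set_index("gene_id")["assigned_phase"]
    out = {}
    for p in PHASES:
        genes = marker_set.per_phase.get(p, [])
        if not genes:
            out[p] = float("nan")
            continue
        out[p] = float(np.mean([truth.get(g, "") == p for g in genes]))
    return out


def assign_phases(
    cm: CountMatrix, marker_set: mk.MarkerSet, cfg: AnalysisConfig,
) -> pd.DataFrame:
    """Module-score phase calls for every cell of a count matrix."""
    norm = mk.lognormalize(cm)
    return ph.score_cells_by_phase(
        norm, cm.gene_ids, cm.cell_ids, marker_set, seed=cfg.seed,
        n_bins=cfg.score_n_bins, ctrl_size=cfg.score_ctrl_size,
    )


def bulk_concordance_run(
    sim_cfg: sim.SimulationConfig, marker_set: mk.MarkerSet,
    program: pd.DataFrame, an_cfg: AnalysisConfig,
) -> dict:
    """Simulate ploidy-sorted bulk from the shared truth and score agreement."""
    table, _ = sim.simulate_ploidy_bulk(sim_cfg, replicates=2, program=program)
    tpm = bulk_mod.tpm_normalize(table)
    clusters = bulk_mod.filter_and_cluster(
        tpm, table, k=an_cfg.kmeans_k, seed=an_cfg.seed,
        min_tpm=an_cfg.bulk_min_tpm, var_quantile=an_cfg.bulk_var_quantile,
        n_starts=an_cfg.kmeans_starts,
    )
    result = bulk_mod.concordance(marker_set, clusters)
    result.update({"bulk": table, "tpm": tpm, "clusters": clusters})
    return result


def timelapse_run(
    sim_cfg: sim.SimulationConfig, an_cfg: AnalysisConfig,
    n_tracks: int = 75, movie_hours: float = 15.0, t0_ablated: float = 3.0,
) -> dict:
    """Control vs ablated arms: classification, metrics, survival, log-rank."""
    arms = {}
    for regime in ("control", "ablated"):
        tracks = sim.simulate_placci_tracks(sim_cfg, n_tracks, regime, movie_hours)
        intervals = tl.classify_tracks(tracks, an_cfg)
        metrics = tl.g1_duration_metrics(intervals, movie_hours,
                                         an_cfg.imputed_g1_hours)
        t0 = t0_ablated if regime == "ablated" else 0.0
        curve = tl.g1_exit_survival(intervals, t0=t0)
        arms[regime] = {"tracks": tracks, "intervals": intervals,
                        "metrics": metrics, "curve": curve, "t0": t0}
    lr = tl.logrank(arms["control"]["curve"], arms["ablated"]["curve"])
    return {"arms": arms, "logrank": lr}
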