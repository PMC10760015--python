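"""Marker discovery: QC gates, rank-sum oracle, delta-pct ranking."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from rootcycle import markers as mk
from rootcycle.config import AnalysisConfig
from rootcycle.io import CountMatrix


def _qc_fixture():
    """5 hand-built cells against the study's default thresholds."""
    rng = np.random.default_rng(42)
    n_genes = 3000
    gene_ids = np.array([f"g{i}" for i in range(n_genes - 1)] + ["MT-0"],
                        dtype=object)
    cells = {
        "ok_a": (2500, 0.01, 5000),     # features, mito frac, total
        "too_few": (1500, 0.01, 4000),  # fails the >2000 features gate
        "mito": (2500, 0.06, 5000),     # fails the <5 percent mito gate
        "too_deep": (2500, 0.01, 150_000),  # fails the <100000 molecules gate
        "ok_b": (2800, 0.01, 6000),
    }
    cols = []
    for feats, mito_frac, total in cells.values():
        col = np.zeros(n_genes)
        expressed = rng.choice(n_genes - 1, feats - 1, replace=False)
        weights = rng.dirichlet(np.ones(feats - 1))
        body = np.round(weights * total * (1 - mito_frac)).astype(int)
        body[body == 0] = 1
        col[expressed] = body
        col[-1] = max(1, round(total * mito_frac))
        cols.append(col)
    m = CountMatrix(sp.csr_matrix(np.column_stack(cols)), gene_ids,
                    np.array(list(cells), dtype=object))
    meta = pd.DataFrame({"cell_id": list(cells), "library": "control",
                         "cell_type": "t"})
    return m, meta


def test_qc_gates_remove_the_documented_failures():
    m, meta = _qc_fixture()
    kept, meta_kept, report = mk.filter_cells_qc(m, meta, AnalysisConfig())
    assert set(kept.cell_ids) == {"ok_a", "ok_b"}
    assert report["failed_features"] == 1
    assert report["failed_mito"] >= 1
    assert report["failed_total"] >= 1
    # R squared equals the closed-form Pearson^2 on the kept cells
    feats = np.asarray((kept.counts > 0).sum(axis=0)).ravel()
    totals = np.asarray(kept.counts.sum(axis=0)).ravel()
    expected = np.corrcoef(feats, totals)[0, 1] ** 2
    assert report["r_squared"] == pytest.approx(expected)


def test_qc_empty_result_is_an_error():
    m, meta = _qc_fixture()
    cfg = AnalysisConfig(min_features=2900, max_features=2901)
    with pytest.raises(ValueError, match="every cell"):
        mk.filter_cells_qc(m, meta, cfg)


def test_lognormalize_formula_and_invariances():
    m = CountMatrix(sp.csr_matrix(np.array([[0, 5], [3, 0]])), ["a", "b"],
                    ["c1", "c2"])
    norm = mk.lognormalize(m, scale=10_000)
    assert norm[0, 0] == 0.0
    # a cell expressing a single gene maps to ln(1 + scale) whatever the count
    assert norm[1, 0] == pytest.approx(np.log1p(10_000))
    assert norm[0, 1] == pytest.approx(np.log1p(10_000))
    doubled = CountMatrix(m.counts * 2, m.gene_ids, m.cell_ids)
    np.testing.assert_allclose(mk.lognormalize(doubled), norm)


def test_lognormalize_rejects_zero_total_cell():
    m = CountMatrix(sp.csr_matrix(np.array([[0, 1], [0, 2]])), ["a", "b"],
                    ["empty", "ok"])
    with pytest.raises(ValueError, match="empty"):
        mk.lognormalize(m)


def _meta(counts_by_lib_type):
    rows = []
    for (lib, ct), n in counts_by_lib_type.items():
        for i in range(n):
            rows.append({"cell_id": f"{lib}_{ct}_{i}", "library": lib,
                         "cell_type": ct})
    return pd.DataFrame(rows)


def test_equalize_min_rule():
    meta = _meta({("G1_enriched", "t"): 10, ("S_enriched", "t"): 7,
                  ("G2M_enriched", "t"): 12})
    kept = mk.equalize_composition(meta, seed=0)
    out = meta[meta["cell_id"].isin(kept)]
    assert out.groupby("library").size().tolist() == [7, 7, 7]


def test_equalize_identity_when_already_equal():
    meta = _meta({("G1_enriched", "t"): 5, ("S_enriched", "t"): 5})
    kept = mk.equalize_composition(meta, seed=1)
    assert set(kept) == set(meta["cell_id"])


def test_equalize_seed_contract():
    meta = _meta({("G1_enriched", "t"): 10, ("S_enriched", "t"): 4,
                  ("G1_enriched", "u"): 6, ("S_enriched", "u"): 6})
    a = mk.equalize_composition(meta, seed=7)
    b = mk.equalize_composition(meta, seed=7)
    c = mk.equalize_composition(meta, seed=8)
    np.testing.assert_array_equal(a, b)
    # different seeds may pick different cells but identical stratum counts
    ma = meta[meta["cell_id"].isin(a)].groupby(["library", "cell_type"]).size()
    mc = meta[meta["cell_id"].isin(c)].groupby(["library", "cell_type"]).size()
    pd.testing.assert_series_equal(ma, mc)


def test_equalize_drops_type_missing_from_a_library():
    meta = _meta({("G1_enriched", "t"): 5, ("S_enriched", "t"): 5,
                  ("G1_enriched", "only_here"): 4})
    with pytest.warns(UserWarning, match="only_here"):
        kept = mk.equalize_composition(meta, seed=0)
    assert not any("only_here" in k for k in kept)


# ---------------------------------------------------------------------------
# rank-sum oracle
# ---------------------------------------------------------------------------

def _exact_ranksum_p(x, y):
    """Two-sided p by exhaustive enumeration of all label assignments."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(pooled)
    ranks = stats.rankdata(pooled)
    obs = ranks[:n].sum()
    center = n * (m + 1) / 2
    stat_obs = abs(obs - center)
    count = total = 0
    for idx in itertools.combinations(range(m), n):
        s = ranks[list(idx)].sum()
        count += abs(s - center) >= stat_obs - 1e-12
        total += 1
    return count / total


def test_ranksum_separated_groups_match_enumeration():
    x, y = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
    p = mk._ranksum_pvalues(x[None, :], y[None, :])[0]
    assert p == pytest.approx(_exact_ranksum_p(x, y))
    assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments are as extreme


@pytest.mark.parametrize("n,m,seed", [(3, 3, 0), (4, 5, 1), (5, 5, 2),
                                      (6, 4, 3), (8, 8, 4)])
def test_ranksum_matches_enumeration_small_groups(n, m, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = rng.normal(size=m)
    p = mk._ranksum_pvalues(x[None, :], y[None, :])[0]
    assert p == pytest.approx(_exact_ranksum_p(x, y), abs=1e-12)


def test_ranksum_constant_gene_p_one():
    x = np.ones((1, 30))
    y = np.ones((1, 50))
    assert mk._ranksum_pvalues(x, y)[0] == 1.0


def test_de_identical_groups_filtered(small_analysis_cfg):
    rng = np.random.default_rng(0)
    vec = rng.poisson(3, 60).astype(float)
    norm = np.tile(vec, (5, 1))
    meta = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(60)],
        "library": (["G1_enriched"] * 15 + ["S_enriched"] * 15 +
                    ["G2M_enriched"] * 15 + ["control"] * 15),
        "cell_type": "t",
    })
    out = mk.de_one_vs_rest(norm, np.array([f"g{i}" for i in range(5)], dtype=object),
                            meta, small_analysis_cfg)
    assert out.empty  # permuted labels of one vector cannot be markers


def test_de_recovers_planted_gene(small_libraries, small_analysis_cfg):
    cm, meta, program = small_libraries
    norm = mk.lognormalize(cm)
    records = mk.de_one_vs_rest(norm, cm.gene_ids, meta, small_analysis_cfg)
    g1_planted = set(program[program["assigned_phase"] == "G1"]["gene_id"])
    found = set(records[records["phase"] == "G1"]["gene_id"])
    assert len(g1_planted & found) / len(g1_planted) > 0.8


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def _record(gene, phase, delta, p=1e-5, lfc=1.0, pct_in=0.9, mean_in=1.0):
    return {"gene_id": gene, "phase": phase, "p_value": p, "lfc": lfc,
            "pct_in": pct_in, "pct_out": pct_in - delta, "delta_pct": delta,
            "mean_in": mean_in, "q_value": p, "significant": True}


def test_delta_pct_definition_and_tie_break():
    recs = pd.DataFrame([
        _record("g1", "G1", 0.8, p=1e-4),
        _record("g2", "G1", 0.8, p=1e-8),
        _record("g3", "G1", 0.5),
    ])
    ms = mk.select_markers(recs, top_n=2)
    assert recs.loc[0, "pct_in"] - recs.loc[0, "pct_out"] == pytest.approx(0.8)
    assert ms.per_phase["G1"] == ["g2", "g1"]  # smaller p wins the tie


def test_select_markers_order_invariant_and_disjoint():
    rng = np.random.default_rng(5)
    recs = pd.DataFrame([
        _record(f"g{i}", phase, rng.uniform(0.1, 0.9), p=rng.uniform(1e-8, 1e-3))
        for i in range(30) for phase in ("G1", "S")
    ])
    a = mk.select_markers(recs, top_n=10)
    b = mk.select_markers(recs.sample(frac=1, random_state=1), top_n=10)
    assert a.per_phase == b.per_phase
    assert not (set(a.per_phase["G1"]) & set(a.per_phase["S"]))


def test_multi_phase_gene_goes_to_max_delta():
    recs = pd.DataFrame([
        _record("g1", "G1", 0.4),
        _record("g1", "S", 0.6),
    ])
    ms = mk.select_markers(recs, top_n=5)
    assert ms.per_phase["S"] == ["g1"]
    assert ms.per_phase["G1"] == []


def test_short_list_warns():
    recs = pd.DataFrame([_record("g1", "G1", 0.5)])
    with pytest.warns(UserWarning, match="markers survive"):
        ms = mk.select_markers(recs, top_n=50)
    assert ms.per_phase["G1"] == ["g1"]


def test_probe_candidate_gates_are_strict():
    recs = pd.DataFrame([
        _record("borderline_pct", "G1", 0.5, pct_in=0.79, lfc=1.0),
        _record("borderline_lfc", "G1", 0.5, pct_in=0.9, lfc=0.25),
        _record("passes", "G1", 0.5, pct_in=0.80, lfc=0.26),
    ])
    out = mk.select_probe_candidates(recs)
    assert out["gene_id"].tolist() == ["passes"]


def test_probe_candidates_top5_by_in_phase_mean():
    recs = pd.DataFrame([
        _record(f"g{i}", "G1", 0.5, pct_in=0.9, lfc=1.0, mean_in=float(i))
        for i in range(7)
    ])
    out = mk.select_probe_candidates(recs)
    assert out["gene_id"].tolist() == ["g6", "g5", "g4", "g3", "g2"]
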