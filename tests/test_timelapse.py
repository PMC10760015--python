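"""Track classification, censoring-aware intervals, survival machinery."""

import numpy as np
import pytest

from rootcycle import simulate as sim
from rootcycle import timelapse as tl
from rootcycle.config import AnalysisConfig
from rootcycle.io import NucleusTrack


def _track(cfp, mcherry, yfp, dt=1.0):
    n = len(cfp)
    t = np.arange(n) * dt
    return NucleusTrack("t0", "f0", t, cfp, mcherry, yfp,
                        np.zeros(n), np.zeros(n))


def test_classification_rule():
    track = _track(cfp=[100, 10, 10], mcherry=[10, 10, 10], yfp=[10, 10, 100])
    frames = tl.classify_frames(track, smooth_window=1)
    assert list(frames["label"]) == ["G1", "S_or_early_G2", "G2M"]
    assert not frames["conflict"].any()


def test_conflict_resolved_by_normalized_excess():
    track = _track(cfp=[100, 60, 60], mcherry=[10] * 3, yfp=[90, 60, 200])
    frames = tl.classify_frames(track, smooth_window=1)
    assert frames.loc[0, "label"] == "G1"    # cfp excess 1.0 > yfp excess 0.8
    assert frames.loc[2, "label"] == "G2M"
    assert frames.loc[0, "conflict"] and frames.loc[2, "conflict"]


def test_majority_smoothing_removes_flicker():
    cfp = [100, 100, 10, 100, 100, 10, 10, 10]
    track = _track(cfp=cfp, mcherry=[10] * 8, yfp=[10] * 8)
    frames = tl.classify_frames(track, smooth_window=3)
    assert list(frames["label"][:5]) == ["G1"] * 5
    assert list(frames["label"][5:]) == ["S_or_early_G2"] * 3


def test_noiseless_track_recovers_truth_timeline(small_sim_cfg):
    cfg = sim.SimulationConfig(**{**small_sim_cfg.__dict__,
                                  "channel_noise_sd": 0.0})
    tracks = sim.simulate_placci_tracks(cfg, 8, "control", 12.0)
    an = AnalysisConfig(smooth_window=1)
    for t in tracks:
        frames = tl.classify_frames(t, an)
        for _, seg in t.truth.iterrows():
            mask = (frames["time_h"] >= seg.start_h) & (frames["time_h"] < seg.end_h)
            expect = {"G1": "G1", "S_early_G2": "S_or_early_G2",
                      "G2M_late": "G2M"}[seg.emission_state]
            assert (frames.loc[mask, "label"] == expect).all()


def test_interval_midpoint_convention():
    labels = np.array(["G1", "G1", "S_or_early_G2", "S_or_early_G2"], dtype=object)
    ivs = tl.extract_intervals(labels, np.array([0.0, 1.0, 2.0, 3.0]), "t")
    assert len(ivs) == 2
    g1, s = ivs
    assert (g1.start, g1.end) == (0.0, 1.5)
    assert g1.left_censored and not g1.right_censored
    assert (s.start, s.end) == (1.5, 3.0)
    assert s.right_censored and not s.left_censored


def test_single_label_doubly_censored():
    ivs = tl.extract_intervals(np.array(["G1"] * 4, dtype=object),
                               np.arange(4.0), "t")
    assert len(ivs) == 1
    assert ivs[0].left_censored and ivs[0].right_censored


def test_interval_reconstruction_matches_truth(small_sim_cfg):
    """Noiseless boundaries agree with truth within one frame interval."""
    cfg = sim.SimulationConfig(**{**small_sim_cfg.__dict__,
                                  "channel_noise_sd": 0.0})
    tracks = sim.simulate_placci_tracks(cfg, 10, "control", 12.0)
    an = AnalysisConfig(smooth_window=1)
    for t in tracks:
        frames = tl.classify_frames(t, an)
        ivs = tl.extract_intervals(frames["label"].to_numpy(),
                                   frames["time_h"].to_numpy(), t.track_id)
        truth_g1 = t.truth[(t.truth["true_phase"] == "G1")]
        for iv in ivs:
            if iv.phase != "G1" or iv.left_censored or iv.right_censored:
                continue
            match = truth_g1[(truth_g1["start_h"] - iv.start).abs() < 0.5]
            assert len(match) == 1
            seg = match.iloc[0]
            assert abs(iv.duration - (seg.end_h - seg.start_h)) <= cfg.frame_interval_h + 1e-9


def test_g1_metric_rules():
    ivs = {
        "a": [tl.PhaseInterval("a", "G1", 1.0, 3.0, False, False)],
        "b": [tl.PhaseInterval("b", "G1", 15.0, 20.0, False, True)],
        "c": [tl.PhaseInterval("c", "G1", 0.0, 4.0, True, False)],  # excluded
    }
    m = tl.g1_duration_metrics(ivs, movie_span=20.0, imputed_value=20.0)
    assert set(m["track_id"]) == {"a", "b"}
    a = m[m["track_id"] == "a"].iloc[0]
    assert (a.metric1_elapsed_h, a.metric2_imputed_h,
            a.metric3_movie_fraction) == (2.0, 2.0, 0.1)
    b = m[m["track_id"] == "b"].iloc[0]
    assert (b.metric1_elapsed_h, b.metric2_imputed_h,
            b.metric3_movie_fraction) == (5.0, 20.0, 0.25)


def test_km_hand_computed_no_censoring():
    curve = tl.km_curve(np.array([1.0, 2.0]), np.array([True, True]))
    assert curve.survival_at(1.0) == pytest.approx(0.5)
    assert curve.survival_at(2.0) == pytest.approx(0.0)


def test_km_hand_computed_with_censoring():
    # events at 1 and 2, censored at 1.5: S(1)=2/3, S(2)=(2/3)*(1-1/1)=0
    curve = tl.km_curve(np.array([1.0, 1.5, 2.0]),
                        np.array([True, False, True]))
    assert curve.survival_at(1.0) == pytest.approx(2 / 3)
    assert curve.survival_at(2.0) == pytest.approx(0.0)


def test_km_all_censored_is_flat_one():
    curve = tl.km_curve(np.array([1.0, 2.0, 3.0]), np.array([False] * 3))
    assert curve.survival_at(5.0) == 1.0
    assert len(curve.event_times) == 0


def test_km_monotone_on_random_data(rng):
    durations = rng.exponential(5, 60)
    observed = rng.random(60) < 0.6
    curve = tl.km_curve(durations, observed)
    assert np.all(np.diff(curve.survival) <= 1e-12)
    assert np.all((curve.survival >= 0) & (curve.survival <= 1))


def _logrank_oracle(times_a, times_b):
    """Direct observed/expected/variance tabulation, no censoring."""
    all_times = np.unique(np.concatenate([times_a, times_b]))
    O_E = V = 0.0
    for t in all_times:
        n_a = (times_a >= t).sum()
        n_b = (times_b >= t).sum()
        d_a = (times_a == t).sum()
        d_b = (times_b == t).sum()
        n, d = n_a + n_b, d_a + d_b
        O_E += d_a - d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return O_E ** 2 / V


def test_logrank_identical_groups_null():
    t = np.array([1.0, 2.0, 3.0])
    a = tl.km_curve(t, np.ones(3, bool))
    b = tl.km_curve(t, np.ones(3, bool))
    res = tl.logrank(a, b)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_matches_oev_tabulation():
    ta = np.array([1.0, 2.0])
    tb = np.array([3.0, 4.0])
    a = tl.km_curve(ta, np.ones(2, bool))
    b = tl.km_curve(tb, np.ones(2, bool))
    res = tl.logrank(a, b)
    assert res.statistic == pytest.approx(_logrank_oracle(ta, tb), abs=1e-10)


def test_logrank_label_swap_invariant(rng):
    ta = rng.exponential(3, 25)
    tb = rng.exponential(6, 25)
    a = tl.km_curve(ta, np.ones(25, bool))
    b = tl.km_curve(tb, np.ones(25, bool))
    assert tl.logrank(a, b).statistic == pytest.approx(
        tl.logrank(b, a).statistic)


def test_logrank_zero_events_convention():
    a = tl.km_curve(np.array([1.0, 2.0]), np.array([False, False]))
    b = tl.km_curve(np.array([3.0]), np.array([False]))
    res = tl.logrank(a, b)
    assert (res.statistic, res.p_value) == (0.0, 1.0)


def test_g1_exit_risk_set_fixed_at_t0():
    ivs = {
        "in_g1": [tl.PhaseInterval("in_g1", "G1", 0.0, 4.0, True, False)],
        "late_g1": [tl.PhaseInterval("late_g1", "S_or_early_G2", 0.0, 2.0, True, False),
                    tl.PhaseInterval("late_g1", "G1", 2.0, 6.0, False, False)],
    }
    curve = tl.g1_exit_survival(ivs, t0=0.0)
    assert len(curve.durations) == 1  # only the cell already in G1 at t0
    assert curve.durations[0] == 4.0


def test_g1_exit_empty_risk_set_is_an_error():
    ivs = {"t": [tl.PhaseInterval("t", "S_or_early_G2", 0.0, 5.0, True, True)]}
    with pytest.raises(ValueError, match="no track"):
        tl.g1_exit_survival(ivs, t0=0.0)
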