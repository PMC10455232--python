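"""Flowrate estimation, flow-stop detection rules, endpoint derivation."""

import numpy as np
import pytest

from cathflow.errors import DataError
from cathflow.flowstop import (
    DetectorConfig,
    count_flow_stops,
    derive_endpoints,
    detect_flow_stops,
    estimate_flowrate,
)
from cathflow.profile_io import ClinicalRecord, ProfileTrace
from cathflow.reference import naive_flow_stop_intervals
from cathflow.synth import ProfileSimConfig, simulate_profile


def naive_to_tuples(trace, intervals):
    t = trace.t
    out = []
    for i0, i1, term in intervals:
        t_end = t[i1 + 1] if i1 + 1 < len(t) else t[-1]
        out.append((float(t[i0]), float(t_end), term))
    return out


def prod_to_tuples(episodes):
    return [(e.t_start, e.t_end, e.terminal) for e in episodes]


class TestEstimateFlowrate:
    def test_exact_slope_of_linear_volume(self, flow_trace):
        tr = flow_trace([(26, 2.0)])  # v(t) = 2t over ~10 s
        q = estimate_flowrate(tr)
        np.testing.assert_allclose(q[2:-2], 2.0, atol=1e-12)

    def test_constant_volume_gives_zero_flowrate(self):
        t = np.arange(20) * 0.4
        tr = ProfileTrace("s", "CEC", 1, t=t, v=np.full(20, 5.0), p=np.zeros(20))
        np.testing.assert_allclose(estimate_flowrate(tr), 0.0, atol=1e-10)

    def test_noisy_ramp_slope_matches_windowed_regression_oracle(self, rng):
        # slope-3 ramp with sigma=0.2 g scale noise
        t = np.arange(0, 60, 0.4)
        v_noisy = np.maximum.accumulate(np.clip(3.0 * t + rng.normal(0, 0.2, t.size), 0, None))
        tr = ProfileTrace("s", "CEC", 1, t=t, v=v_noisy, p=np.zeros_like(t))
        cfg = DetectorConfig()
        q = estimate_flowrate(tr, cfg)
        assert abs(q[3:-3].mean() - 3.0) < 0.05
        # oracle: per-sample polyfit over the same +/-0.6 s windows
        for i in range(3, len(t) - 3, 7):
            sel = np.abs(t - t[i]) <= cfg.smooth_halfwidth
            slope = np.polyfit(t[sel], v_noisy[sel], 1)[0]
            assert q[i] == pytest.approx(max(slope, 0.0), abs=1e-8)

    def test_trace_shorter_than_window_is_a_data_error(self):
        tr = ProfileTrace("s", "CEC", 1, t=[0.0, 0.4], v=[0.0, 1.0], p=[0.0, 0.0])
        with pytest.raises(DataError):
            estimate_flowrate(tr, DetectorConfig(smooth_halfwidth=5.0))

    def test_flowrate_clipped_at_zero(self, rng):
        t = np.arange(30) * 0.4
        v = np.maximum.accumulate(rng.normal(0, 0.01, 30).cumsum().clip(0, None))
        tr = ProfileTrace("s", "CEC", 1, t=t, v=v, p=np.zeros(30))
        assert (estimate_flowrate(tr) >= 0).all()


class TestDetectFlowStops:
    def test_steady_flow_then_cessation_gives_single_terminal_episode(self, flow_trace):
        tr = flow_trace([(100, 1.5), (20, 0.0)])
        eps = detect_flow_stops(tr)
        assert len(eps) == 1
        assert eps[0].terminal
        assert count_flow_stops(eps) == 0

    def test_dip_shorter_than_minimum_duration_is_not_an_episode(self, flow_trace):
        # 5 sub-threshold samples at dt=0.38 s: a 1.9 s dip, below the 2 s rule
        tr = flow_trace([(40, 3.0), (5, 0.6), (40, 3.0), (15, 0.0)], dt=0.38)
        eps = detect_flow_stops(tr)
        assert len(eps) == 1 and eps[0].terminal

    def test_dip_longer_than_minimum_duration_is_an_episode(self, flow_trace):
        # 7 sub-threshold input samples leave a 2.28 s >= 2 s detected run
        # (the smoothing window absorbs one edge sample)
        tr = flow_trace([(40, 3.0), (7, 0.6), (40, 3.0), (15, 0.0)], dt=0.38)
        eps = detect_flow_stops(tr)
        assert len(eps) == 2
        assert [e.terminal for e in eps] == [False, True]
        assert count_flow_stops(eps) == 1

    def test_no_flow_onset_yields_whole_trace_terminal_episode(self, flow_trace):
        tr = flow_trace([(30, 0.1)])
        eps = detect_flow_stops(tr)
        assert len(eps) == 1
        assert eps[0].terminal
        assert eps[0].t_start == tr.t[0] and eps[0].t_end == tr.t[-1]
        assert count_flow_stops(eps) == 0

    def test_injected_stops_recovered_with_onsets_within_one_sample(self, rng):
        cfg = ProfileSimConfig()
        tr, truth = simulate_profile(
            cfg, "CEC", rng, targets={"n_flow_stops": 2, "rv1": 80.0}
        )
        eps = detect_flow_stops(tr)
        assert count_flow_stops(eps) == 2
        dt = 1.0 / cfg.sampling_rate
        for ep, ev in zip(eps[:-1], truth.events):
            assert abs(ep.t_start - ev.t_start) <= dt + 1e-9

    def test_pre_onset_dead_time_is_not_an_episode(self, flow_trace):
        # 8 s of zero flow before drainage starts must not count as a stop
        tr = flow_trace([(20, 0.0), (80, 2.0), (15, 0.0)])
        eps = detect_flow_stops(tr)
        assert len(eps) == 1 and eps[0].terminal

    def test_episodes_disjoint_ordered_and_suction_nonpositive(self, sim_corpus):
        for tr, _ in sim_corpus[:40]:
            eps = detect_flow_stops(tr)
            for a, b in zip(eps, eps[1:]):
                assert a.t_end <= b.t_start
            assert all(e.peak_suction <= 0 for e in eps)
            assert all(e.duration >= DetectorConfig().min_duration for e in eps)
            assert all(e.min_flowrate < DetectorConfig().flow_threshold for e in eps)


class TestDetectorOracleEquivalence:
    def test_matches_naive_per_sample_scan_on_simulated_corpus(self, sim_corpus):
        for tr, _ in sim_corpus:
            prod = prod_to_tuples(detect_flow_stops(tr))
            naive = naive_to_tuples(tr, naive_flow_stop_intervals(tr))
            assert prod == naive

    def test_matches_naive_scan_under_varied_detector_configs(self, sim_corpus):
        cfgs = [
            DetectorConfig(flow_threshold=0.5),
            DetectorConfig(flow_threshold=1.1, min_duration=3.0),
            DetectorConfig(merge_gap=1.2),
        ]
        for tr, _ in sim_corpus[:30]:
            for cfg in cfgs:
                prod = prod_to_tuples(detect_flow_stops(tr, cfg))
                naive = naive_to_tuples(tr, naive_flow_stop_intervals(tr, cfg))
                assert prod == naive


def test_raising_threshold_never_shrinks_covered_time(sim_corpus):
    for tr, _ in sim_corpus[:40]:
        covered = []
        for thr in (0.5, 0.8, 1.1):
            eps = detect_flow_stops(tr, DetectorConfig(flow_threshold=thr))
            covered.append(sum(e.duration for e in eps))
        assert covered[0] <= covered[1] + 1e-9
        assert covered[1] <= covered[2] + 1e-9


class TestCountFlowStops:
    def test_single_terminal_episode_counts_as_zero(self, flow_trace):
        eps = detect_flow_stops(flow_trace([(60, 1.5), (15, 0.0)]))
        assert count_flow_stops(eps) == 0

    def test_two_stops_plus_terminal_count_as_two(self, rng):
        tr, _ = simulate_profile(
            ProfileSimConfig(), "CEC", rng, targets={"n_flow_stops": 2, "rv1": 60.0}
        )
        assert count_flow_stops(detect_flow_stops(tr)) == 2

    def test_empty_episode_list_counts_zero(self):
        assert count_flow_stops([]) == 0


class TestDeriveEndpoints:
    def test_rv1_is_total_minus_first_onset_volume(self, flow_trace):
        # 260 mL drained at 2 mL/s, a 5 s stop, then 40 mL more: rv1 = 40
        tr = flow_trace([(325, 2.0), (13, 0.0), (50, 2.0), (15, 0.0)])
        eps = detect_flow_stops(tr)
        out = derive_endpoints(tr, eps)
        assert out.v_first_stop == pytest.approx(260.0, abs=2.0)
        assert out.rv1 == pytest.approx(out.v_total - out.v_first_stop)
        assert out.rv1 == pytest.approx(40.0, abs=2.5)

    def test_rv1_conservation_and_nonnegativity_on_corpus(self, sim_corpus):
        for tr, _ in sim_corpus:
            out = derive_endpoints(tr, detect_flow_stops(tr))
            assert out.rv1 == pytest.approx(out.v_total - out.v_first_stop, abs=1e-12)
            assert out.rv1 >= 0
            assert out.n_flow_stops >= 0

    def test_terminal_dribble_recovered_as_rv1(self, rng):
        tr, truth = simulate_profile(
            ProfileSimConfig(), "MHZC", rng, targets={"n_flow_stops": 0, "rv1": 12.0}
        )
        out = derive_endpoints(tr, detect_flow_stops(tr))
        one_sample_volume = ProfileSimConfig().plateau_flow[1] / ProfileSimConfig().sampling_rate
        assert abs(out.rv1 - 12.0) <= one_sample_volume

    def test_clinical_record_attaches_haematuria_and_residual(self, flow_trace):
        tr = flow_trace([(100, 2.0), (15, 0.0)])
        rec = ClinicalRecord("T", 1, "CEC", (200, 210, 190), (4.0, 6.0, 5.0),
                             "haemolysed 80 (2+)")
        out = derive_endpoints(tr, detect_flow_stops(tr), rec)
        assert out.haematuria_positive is True
        assert out.postvoid_residual == pytest.approx(5.0)

    def test_no_episodes_is_a_precondition_error(self, flow_trace):
        with pytest.raises(DataError):
            derive_endpoints(flow_trace([(100, 2.0), (15, 0.0)]), [])
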