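"""Track segmentation, event counting, aggregation and condition comparison."""

import math

import numpy as np
import pytest

from mtxkit.dynamics import (
    DynamicsParams, MicrotubuleDynamics, Track, aggregate_params,
    compare_conditions, phase_labels, round_percent, segment_track,
    significance_code, track_events, tracks_from_frame,
)
from mtxkit.simulate import DIParams, simulate_tracks

#: Published-style control vs high-dose statistic means used for the
#: percent-change arithmetic checks.
CONTROL_MEANS = dict(growth_rate=25.9, shortening_rate=31.1,
                     growth_length=1.87, shortening_length=1.59,
                     pct_time_G=28.7, pct_time_S=17.3, pct_time_P=53.6,
                     cat_per_min=4.65, res_per_min=18.91,
                     cat_per_um=0.75, res_per_um=0.93, dynamicity=14.4)
TREATED_MEANS = dict(growth_rate=20.3, shortening_rate=24.5,
                     growth_length=1.12, shortening_length=1.19,
                     pct_time_G=20.5, pct_time_S=17.7, pct_time_P=61.9,
                     cat_per_min=4.81, res_per_min=20.24,
                     cat_per_um=1.07, res_per_um=1.58, dynamicity=8.65)


def piecewise_track(phases, dt=1.0, l0=5.0, track_id="t0"):
    """Build a noiseless track from (phase, duration_s, rate_um_min) tuples."""
    t = [0.0]
    y = [l0]
    for _, dur, rate in phases:
        n = int(round(dur / dt))
        for _ in range(n):
            t.append(t[-1] + dt)
            y.append(y[-1] + rate / 60.0 * dt)
    return Track(track_id=track_id, time=np.array(t), length=np.array(y))


class TestSegmentTrack:
    def test_constant_track_is_single_pause(self):
        tr = Track("t", np.arange(11.0), np.full(11, 4.0))
        segs = segment_track(tr)
        assert len(segs) == 1
        assert segs[0].phase == "P"
        assert (segs[0].t_start, segs[0].t_end) == (0.0, 10.0)

    def test_piecewise_linear_exact_recovery(self):
        spec = [("G", 10, 30.0), ("P", 10, 0.0), ("S", 8, -45.0), ("G", 12, 24.0)]
        tr = piecewise_track(spec)
        segs = segment_track(tr, min_excursion=0.5, min_rate=2.0)
        assert [s.phase for s in segs] == [p for p, _, _ in spec]
        bounds = np.cumsum([0] + [d for _, d, _ in spec])
        for seg, t0, t1, (_, _, rate) in zip(segs, bounds[:-1], bounds[1:], spec):
            assert (seg.t_start, seg.t_end) == (t0, t1)
            assert seg.rate == pytest.approx(rate, abs=1e-9)

    def test_small_excursion_demoted_to_pause(self):
        # a 0.2 µm blip does not count as growth at the 0.5 µm threshold
        tr = piecewise_track([("P", 10, 0.0), ("G", 2, 6.0), ("P", 10, 0.0)])
        segs = segment_track(tr, min_excursion=0.5, min_rate=2.0)
        assert [s.phase for s in segs] == ["P"]

    def test_partition_invariants(self):
        ts = simulate_tracks(DIParams(), 20, seed=3)
        for tr in ts.to_tracks():
            segs = segment_track(tr)
            assert sum(s.duration for s in segs) == pytest.approx(tr.duration)
            assert sum(s.delta_length for s in segs) == \
                pytest.approx(tr.length[-1] - tr.length[0], abs=1e-9)
            for a, b in zip(segs[:-1], segs[1:]):
                assert a.phase != b.phase
                assert a.t_end == b.t_start

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            Track("t", np.array([0.0, 1.0]), np.array([0.0, 1.0]))

    def test_hidden_state_recovery_on_finely_sampled_tracks(self):
        """Noiseless segmentation recovers the simulator's hidden states.

        Sampling must resolve the phase durations (mean of a few seconds),
        so the recovery study uses a 50 ms grid; tracks that hit the
        zero-length boundary are excluded as documented.
        """
        params = DIParams(noise_sd=0.0, l0=50.0)
        ts = simulate_tracks(params, 50, duration=60, dt=0.05, seed=11,
                             start_state="stationary")
        match = total = 0
        for tr in ts.tracks:
            if tr.hit_boundary:
                continue
            segs = segment_track(tr.to_track(), min_excursion=0.05, min_rate=2.0)
            labels = phase_labels(segs, len(tr.time))
            match += int(np.sum(labels == tr.states))
            total += len(labels)
        assert match / total >= 0.99


class TestTrackEvents:
    def test_single_growth_segment(self):
        tr = piecewise_track([("G", 20, 30.0)])
        ev = track_events(segment_track(tr))
        assert ev.n_catastrophes == 0 and ev.n_rescues == 0
        assert ev.time_in["G"] == pytest.approx(20.0)
        assert ev.time_in["S"] == 0.0 and ev.time_in["P"] == 0.0

    def test_growth_shortening_growth(self):
        tr = piecewise_track([("G", 10, 30.0), ("S", 6, -40.0), ("G", 10, 30.0)])
        ev = track_events(segment_track(tr))
        assert ev.n_catastrophes == 1
        assert ev.n_rescues == 1

    def test_pause_to_shortening_is_catastrophe(self):
        tr = piecewise_track([("P", 10, 0.0), ("S", 6, -40.0), ("P", 10, 0.0)])
        ev = track_events(segment_track(tr))
        assert ev.n_catastrophes == 1
        assert ev.n_rescues == 1  # S -> P is a rescue

    def test_counts_match_simulator_event_log(self):
        """Events are recovered exactly on tracks whose inter-event gaps
        are resolvable by the sampling grid (> 2 dt), noiseless."""
        params = DIParams(noise_sd=0.0, l0=50.0)
        ts = simulate_tracks(params, 50, duration=60, dt=0.05, seed=11,
                             start_state="stationary")
        checked = 0
        for tr in ts.tracks:
            if tr.hit_boundary:
                continue
            times = tr.events["time_s"].to_numpy()
            gaps = np.diff(np.concatenate([[0.0], times, [60.0]]))
            if len(times) and gaps.min() <= 2 * 0.05:
                continue
            ev = track_events(segment_track(tr.to_track(),
                                            min_excursion=0.05, min_rate=2.0))
            pairs = list(zip(tr.events["from_state"], tr.events["to_state"]))
            assert ev.n_catastrophes == sum(1 for a, b in pairs
                                            if b == "S" and a in "GP")
            assert ev.n_rescues == sum(1 for a, b in pairs
                                       if a == "S" and b in "GP")
            checked += 1
        assert checked >= 10


class TestAggregateParams:
    def test_pure_growth_track(self):
        tr = piecewise_track([("G", 60, 24.0)])
        dp = aggregate_params([tr])
        assert dp.dynamicity.mean == pytest.approx(24.0, abs=1e-9)
        assert dp.pct_time_G.mean == 100.0
        assert dp.cat_per_min.mean == 0.0
        assert dp.cat_per_um.mean == 0.0
        assert math.isnan(dp.res_per_min.mean)  # no shortening time: undefined

    def test_pct_time_sums_to_100(self):
        ts = simulate_tracks(DIParams(), 30, seed=8)
        dp = aggregate_params(ts.to_tracks())
        assert dp.pct_time_G.mean + dp.pct_time_S.mean + dp.pct_time_P.mean == \
            pytest.approx(100.0, abs=0.01)

    def test_dynamicity_consistency_with_rates_and_times(self):
        """dynamicity ~ growth_rate * %G/100 + shortening_rate * %S/100."""
        ts = simulate_tracks(DIParams(noise_sd=0.0, l0=50.0), 50, duration=120,
                             dt=0.25, seed=9)
        dp = aggregate_params(ts.to_tracks(), min_excursion=0.1)
        approx = (dp.growth_rate.mean * dp.pct_time_G.mean
                  + dp.shortening_rate.mean * dp.pct_time_S.mean) / 100.0
        assert dp.dynamicity.mean == pytest.approx(approx, rel=0.1)

    def test_rate_scaling_scales_dynamicity(self):
        """Scaling all speeds and rates by 2 (and the grid by 1/2) doubles
        dynamicity exactly: the event sequence is time-compressed."""
        p1 = DIParams(noise_sd=0.0, l0=50.0)
        p2 = DIParams(v_g=p1.v_g * 2, v_s=p1.v_s * 2, k_gs=p1.k_gs * 2,
                      k_gp=p1.k_gp * 2, k_pg=p1.k_pg * 2, k_ps=p1.k_ps * 2,
                      k_sg=p1.k_sg * 2, k_sp=p1.k_sp * 2,
                      noise_sd=0.0, l0=50.0)
        a = simulate_tracks(p1, 10, duration=60, dt=0.5, seed=21)
        b = simulate_tracks(p2, 10, duration=30, dt=0.25, seed=21)
        for ta, tb in zip(a.tracks, b.tracks):
            assert np.allclose(ta.length_obs, tb.length_obs, atol=1e-9)
        # the rate threshold is scaled with the speeds so both analyses
        # classify the (identical) excursions the same way
        da = aggregate_params(a.to_tracks(), min_excursion=0.1, min_rate=2.0)
        db = aggregate_params(b.to_tracks(), min_excursion=0.1, min_rate=4.0)
        assert db.dynamicity.mean == pytest.approx(2 * da.dynamicity.mean,
                                                   rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_params([])


class TestCompareConditions:
    def test_published_percent_changes_reproduced(self):
        control = DynamicsParams.from_means("control", CONTROL_MEANS)
        treated = DynamicsParams.from_means("treated", TREATED_MEANS)
        rep = compare_conditions(control, treated)
        assert rep.pct_change("dynamicity") == -40
        assert rep.pct_change("shortening_rate") == -21
        assert rep.pct_change("shortening_length") == -25
        assert rep.pct_change("growth_length") == -40
        assert rep.pct_change("pct_time_G") == -29
        assert rep.pct_change("pct_time_P") == 15
        assert rep.pct_change("cat_per_um") == 43
        assert rep.pct_change("res_per_um") == 70

    def test_identical_groups(self):
        tr = [piecewise_track([("G", 30, 24.0), ("S", 10, -30.0)],
                              track_id=f"t{i}") for i in range(3)]
        a = aggregate_params(tr, "a")
        b = aggregate_params(tr, "b")
        rep = compare_conditions(a, b)
        assert rep.pct_change("dynamicity") == 0
        assert rep.p_value("dynamicity") == 1.0
        assert rep.table.set_index("parameter").loc["dynamicity", "code"] == ""

    def test_rounding_half_away_from_zero(self):
        assert round_percent(-39.93) == -40
        assert round_percent(42.67) == 43
        assert round_percent(15.5) == 16
        assert round_percent(-15.5) == -16

    def test_significance_codes(self):
        assert significance_code(0.0005) == "A"
        assert significance_code(0.005) == "B"
        assert significance_code(0.04) == "C"
        assert significance_code(0.2) == ""
        assert significance_code(math.nan) == ""


class TestMicrotubuleDynamics:
    def test_fit_returns_per_condition_params_and_comparisons(self):
        frames = []
        for cond, params in [("control", DIParams(noise_sd=0.0)),
                             ("dosed", DIParams(v_g=18.0, v_s=20.0,
                                                noise_sd=0.0))]:
            ts = simulate_tracks(params, 12, seed=4, condition=cond)
            frames.append(ts.to_dataframe())
        import pandas as pd
        df = pd.concat(frames, ignore_index=True)
        res = MicrotubuleDynamics(df, control="control").fit()
        assert set(res.params) == {"control", "dosed"}
        assert set(res.comparisons) == {"dosed"}
        assert res.params["control"].n_tracks == 12
        table = res.to_frame()
        assert {"condition", "parameter", "mean", "sem", "n"} <= set(table.columns)

    def test_missing_column_rejected(self):
        import pandas as pd
        df = pd.DataFrame({"track_id": ["a"], "time_s": [0.0]})
        with pytest.raises(ValueError, match="length_um"):
            tracks_from_frame(df)
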