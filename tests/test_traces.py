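"""Normalization, window extraction, responsiveness, CV and hold dynamics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import tipm
from tipm.traces import (
    eccentric_dynamics,
    extract_peaks,
    normalize,
    responsiveness_test,
    trial_cv,
    window_mean,
)


def _sweep(F, rate=2.2, baseline_s=6.0, hold_s=15.0, transition_ms=5.3,
           response_s=5.0, cell="c0", trial="step_ipsi_30_t0", rep=0, mag=30.0):
    n = len(F)
    return pd.DataFrame({
        "fish_id": "f", "cell_id": cell, "session_id": "s", "age_dpf": 4,
        "trial_id": trial, "repeat_id": rep, "stim_kind": "step",
        "stim_direction": "ipsi", "stim_magnitude_deg": mag,
        "time_s": np.arange(n) / rate, "F": np.asarray(F, float),
        "baseline_s": baseline_s, "hold_s": hold_s, "response_s": response_s,
        "transition_ms": transition_ms, "hemisphere": "left",
    })


class TestNormalize:
    def test_constant_trace_equal_to_f0_gives_zero_dff(self):
        df = _sweep(np.full(60, 123.0))
        out = normalize(df)
        assert np.allclose(out["dff"], 0.0)
        assert np.allclose(out["F0"], 123.0)

    def test_doubled_fluorescence_gives_dff_of_one(self):
        base = np.full(60, 50.0)
        df = _sweep(base)
        df.loc[df["time_s"] >= df["baseline_s"], "F"] = 100.0
        out = normalize(df)
        post = out[out["time_s"] >= out["baseline_s"]]
        assert np.allclose(post["dff"], 1.0)

    def test_f0_is_mean_of_last_5s_of_baseline(self):
        df = _sweep(np.arange(60, dtype=float) + 100.0)
        out = normalize(df)
        in_win = (df["time_s"] >= 1.0) & (df["time_s"] < 6.0)
        assert out["F0"].iloc[0] == pytest.approx(df.loc[in_win, "F"].mean())

    def test_short_baseline_error_names_trial(self):
        df = _sweep(np.full(50, 10.0), baseline_s=3.0, trial="short_trial")
        with pytest.raises(ValueError, match="short_trial"):
            normalize(df)

    def test_nonpositive_f0_rejected(self):
        df = _sweep(np.full(60, 0.0))
        with pytest.raises(ValueError, match="F0"):
            normalize(df)

    def test_anesthetized_scheme_uses_supplied_f0(self):
        df = _sweep(np.full(60, 80.0))
        out = normalize(df, "anesthetized_baseline", {"c0": 40.0})
        assert np.allclose(out["dff"], 1.0)
        with pytest.raises(ValueError, match="f0_source"):
            normalize(df, "anesthetized_baseline")
        with pytest.raises(ValueError, match="missing"):
            normalize(df, "anesthetized_baseline", {"other": 40.0})

    def test_simulator_round_trip_recovers_forward_model(self, noise_free_session):
        _, traces, gt = noise_free_session
        out = normalize(traces)
        one = out[(out["cell_id"] == list(gt)[0])
                  & (out["stim_direction"] == "ipsi")
                  & (out["stim_magnitude_deg"] == 30.0)]
        hold_dff = one[(one["time_s"] > 18.0) & (one["time_s"] < 21.0)]["dff"]
        expected = gt[list(gt)[0]]["tonic_gain_ipsi"] * 30.0
        assert hold_dff.mean() == pytest.approx(expected, rel=0.02)


class TestExtractPeaks:
    def test_zero_dff_gives_zero_peak(self):
        out = normalize(_sweep(np.full(60, 5.0)))
        peaks = extract_peaks(out)
        assert peaks["peak_response"].iloc[0] == 0.0
        assert peaks["baseline_first_1s_mean"].iloc[0] == 0.0

    def test_constant_post_return_dff_gives_that_peak(self):
        df = _sweep(np.full(60, 10.0))
        t_return = 6.0 + 2 * 5.3e-3 + 15.0
        df.loc[df["time_s"] >= t_return, "F"] = 30.0  # dff = 2 after return
        peaks = extract_peaks(normalize(df))
        assert peaks["peak_response"].iloc[0] == pytest.approx(2.0)

    def test_window_mean_matches_hand_enumerated_samples(self):
        # at 2.2 Hz the [t_return, t_return + 1 s) window holds samples
        # 47 (21.36 s) and 48 (21.82 s) for t_return = 21.0106 s
        rng = np.random.default_rng(0)
        F = rng.uniform(50, 150, 60)
        df = _sweep(F)
        out = normalize(df)
        peaks = extract_peaks(out)
        t_return = 6.0 + 2 * 5.3e-3 + 15.0
        idx = [i for i in range(60) if t_return <= i / 2.2 < t_return + 1.0]
        assert idx == [47, 48]
        hand = out["dff"].to_numpy()[idx].mean()
        assert peaks["peak_response"].iloc[0] == pytest.approx(hand, abs=1e-12)

    def test_eccentric_window_is_last_second_of_hold(self):
        df = _sweep(np.full(60, 10.0))
        t_hold_end = 6.0 + 5.3e-3 + 15.0
        in_last = (df["time_s"] >= t_hold_end - 1.0) & (df["time_s"] < t_hold_end)
        df.loc[in_last, "F"] = 20.0
        peaks = extract_peaks(normalize(df), "eccentric_last_1s")
        assert peaks["peak_response"].iloc[0] == pytest.approx(1.0)
        assert (peaks["window"] == "eccentric_last_1s").all()

    def test_empty_window_error_reports_sample_rate(self):
        df = _sweep(np.full(8, 10.0), rate=0.2)  # 5 s between volumes
        with pytest.raises(ValueError, match="sample rate"):
            extract_peaks(normalize(df))

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError, match="dff"):
            extract_peaks(_sweep(np.full(60, 1.0)))

    def test_peak_is_linear_in_dff(self):
        df = normalize(_sweep(np.random.default_rng(1).uniform(50, 150, 60)))
        p1 = extract_peaks(df)["peak_response"].iloc[0]
        df2 = df.copy()
        df2["dff"] = 3.5 * df2["dff"]
        p2 = extract_peaks(df2)["peak_response"].iloc[0]
        assert p2 == pytest.approx(3.5 * p1, abs=1e-12)

    def test_every_sample_in_exactly_one_segment(self, small_session):
        # baseline / stimulus / response windows partition the sweep
        cfg, traces, _ = small_session
        p = cfg.protocols[0]
        one = traces[(traces["trial_id"] == f"step_ipsi_10_t0")
                     & (traces["cell_id"] == traces["cell_id"].iloc[0])
                     & (traces["repeat_id"] == 0)]
        t = one["time_s"].to_numpy()
        in_baseline = t < p.t_ramp_out
        in_stim = (t >= p.t_ramp_out) & (t < p.t_return)
        in_resp = t >= p.t_return
        assert np.all(in_baseline.astype(int) + in_stim + in_resp == 1)


class TestResponsiveness:
    def test_identical_peaks_and_baselines_not_responsive(self):
        r = responsiveness_test(np.ones(6), np.ones(6))
        assert not r.responsive and r.p >= 0.05

    def test_high_gain_low_noise_cell_is_responsive(self):
        neurons = tipm.make_population(1, rng=1, gain_ipsi_range=(0.1, 0.1),
                                       noise_sd=0.05)
        protos = tipm.default_protocols(directions=("ipsi",), magnitudes=(30.0,))
        cfg = tipm.SimulationConfig(protos, neurons, seed=1)
        peaks = extract_peaks(normalize(tipm.simulate_experiment(cfg)[0]))
        r = responsiveness_test(peaks["peak_response"].to_numpy(),
                                peaks["baseline_first_1s_mean"].to_numpy())
        assert r.responsive and r.p < 1e-3

    def test_single_trial_flagged_not_testable(self):
        r = responsiveness_test(np.array([1.0]), np.array([0.0]))
        assert not r.testable

    def test_two_sample_variant(self):
        rng = np.random.default_rng(0)
        r = responsiveness_test(rng.normal(2, 0.1, 8), rng.normal(0, 0.1, 8),
                                paired=False)
        assert r.responsive

    def test_null_cells_rejected_at_about_test_size(self):
        # test size on zero-gain cells should sit near alpha = 0.05
        neurons = tipm.make_population(
            200, rng=7, gain_ipsi_range=(0.0, 0.0),
            gain_contra_range=(0.0, 0.0), phasic_gain_range=(0.0, 0.0),
        )
        protos = tipm.default_protocols(directions=("ipsi",), magnitudes=(30.0,))
        cfg = tipm.SimulationConfig(protos, neurons, seed=13)
        peaks = extract_peaks(normalize(tipm.simulate_experiment(cfg)[0]))
        resp = tipm.responsiveness_table(peaks)
        frac = resp["responsive"].mean()
        assert 0.005 < frac < 0.12


class TestTrialCV:
    def test_identical_peaks_give_zero_cv(self):
        assert trial_cv(np.array([2.0, 2.0, 2.0])) == 0.0

    def test_hand_computed_example(self):
        # sample SD of {1,2,3} is 1, mean is 2
        assert trial_cv(np.array([1.0, 2.0, 3.0])) == pytest.approx(0.5)

    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_scale_invariance(self, a):
        x = np.array([1.0, 2.0, 4.0])
        assert trial_cv(a * x) == pytest.approx(trial_cv(x), rel=1e-9)

    def test_undefined_cases(self):
        assert np.isnan(trial_cv(np.array([1.0])))
        assert np.isnan(trial_cv(np.array([-1.0, 1.0])))


class TestEccentricDynamics:
    def test_plateau_cell_has_near_zero_decay_slope(self):
        t = np.arange(0, 22, 1 / 2.2)
        dff = np.where(t > 6.0, 2.0, 0.0)
        dyn = eccentric_dynamics(t, dff, 6.0, 21.0)
        assert dyn.decay_slope == pytest.approx(0.0, abs=1e-9)

    def test_fast_decay_rate_recovered(self):
        neurons = tipm.make_population(
            1, rng=3, noise_sd=0.0, decay_class="fast_decay",
            decay_rate_range=(0.08, 0.08), gain_ipsi_range=(0.1, 0.1),
            phasic_gain_range=(0.0, 0.0),
        )
        protos = tipm.default_protocols(directions=("ipsi",), magnitudes=(30.0,))
        cfg = tipm.SimulationConfig(protos, neurons, seed=1,
                                    trials_per_magnitude=1, repeats_per_trial=1)
        traces, _ = tipm.simulate_experiment(cfg)
        ntr = tipm.normalize(traces, "anesthetized_baseline",
                             {neurons[0].cell_id: neurons[0].baseline_F})
        table = tipm.eccentric_dynamics_table(ntr)
        assert table["decay_slope"].iloc[0] == pytest.approx(-0.08, rel=0.25)

    def test_monotonically_rising_trace_peaks_at_hold_end(self):
        t = np.arange(0, 22, 1 / 2.2)
        dyn = eccentric_dynamics(t, t.copy(), 6.0, 21.0)
        assert dyn.time_to_peak_s == pytest.approx(15.0, abs=1.0)

    def test_short_hold_rejected(self):
        t = np.arange(0, 10, 0.5)
        with pytest.raises(ValueError, match="hold"):
            eccentric_dynamics(t, t, 2.0, 7.0)


def test_window_mean_empty_is_nan():
    assert np.isnan(window_mean(np.array([0.0, 1.0]), np.array([1.0, 2.0]), 5.0, 6.0))
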