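"""Shuffle-null sensitivity-change classification and conditional analyses."""

import numpy as np
import pandas as pd
import pytest

import tipm
from tipm.longitudinal import (
    change_correlation,
    classify_cells,
    classify_change,
    early_tuned,
    early_tuned_split,
    shuffle_null,
    single_age_null,
)


def _peaks_df(cell, direction, mags, peaks, age=4):
    return pd.DataFrame({
        "fish_id": "f", "cell_id": cell, "session_id": f"s{age}", "age_dpf": age,
        "trial_id": [f"t{i}" for i in range(len(mags))], "repeat_id": 0,
        "stim_kind": "step", "stim_direction": direction,
        "stim_magnitude_deg": np.asarray(mags, float),
        "peak_response": np.asarray(peaks, float),
        "baseline_first_1s_mean": 0.0, "window": "post_return_first_1s",
    })


MAGS = np.repeat([10.0, 20.0, 30.0], 6)


class TestShuffleNull:
    def test_reproducible_from_seed(self):
        rng = np.random.default_rng(0)
        y1, y2 = rng.normal(1, 0.3, 18), rng.normal(1, 0.3, 18)
        a = shuffle_null(MAGS, y1, MAGS, y2, 500, rng=7)
        b = shuffle_null(MAGS, y1, MAGS, y2, 500, rng=7)
        assert np.array_equal(a.deltas, b.deltas)

    def test_zero_variance_peaks_collapse_cutoffs_without_crashing(self):
        null = shuffle_null(MAGS, np.ones(18), MAGS, np.ones(18), 200, rng=1)
        assert null.sd == 0.0
        assert null.cutoff_lo == null.cutoff_hi == null.mean

    def test_single_magnitude_rejected(self):
        with pytest.raises(ValueError, match="magnitudes"):
            shuffle_null([30] * 4, np.ones(4), MAGS, np.ones(18), 10, rng=0)

    def test_null_centred_near_zero_when_ages_exchangeable(self):
        rng = np.random.default_rng(3)
        y = 0.05 * MAGS
        null = shuffle_null(MAGS, y + rng.normal(0, 0.2, 18),
                            MAGS, y + rng.normal(0, 0.2, 18), 2000, rng=5)
        assert abs(null.mean) < 0.5 * null.sd


class TestClassifyChange:
    def test_delta_at_null_mean_is_no_change(self):
        null = tipm.ShuffleNull(np.zeros(10), 0.01, 0.005, 10)
        assert classify_change(0.01, null).category == "no_change"

    def test_delta_three_sds_up_is_increase(self):
        null = tipm.ShuffleNull(np.zeros(10), 0.0, 0.01, 10)
        assert classify_change(0.03, null).category == "increase"
        assert classify_change(-0.03, null).category == "decrease"

    def test_cutoffs_are_mean_plus_minus_two_sds(self):
        null = tipm.ShuffleNull(np.zeros(10), 0.2, 0.1, 10)
        cls = classify_change(0.0, null)
        assert cls.cutoff_lo == pytest.approx(0.0)
        assert cls.cutoff_hi == pytest.approx(0.4)


class TestClassifyCells:
    def test_exchangeable_trial_order_leaves_delta_unchanged(self):
        rng = np.random.default_rng(1)
        y1, y2 = rng.normal(1, 0.2, 18), rng.normal(1.5, 0.2, 18)
        a1 = _peaks_df("c", "ipsi", MAGS, y1, age=4)
        a2 = _peaks_df("c", "ipsi", MAGS, y2, age=7)
        perm = rng.permutation(18)
        a1p = _peaks_df("c", "ipsi", MAGS[perm], y1[perm], age=4)
        d1 = classify_cells(a1, a2, directions=("ipsi",), n_shuffles=50, seed=0)
        d2 = classify_cells(a1p, a2, directions=("ipsi",), n_shuffles=50, seed=0)
        assert d1["delta_slope"].iloc[0] == pytest.approx(
            d2["delta_slope"].iloc[0], abs=1e-12
        )

    def test_same_seed_reproduces_categories_and_cutoffs(self):
        rng = np.random.default_rng(2)
        a1 = _peaks_df("c", "ipsi", MAGS, rng.normal(1, 0.3, 18), age=4)
        a2 = _peaks_df("c", "ipsi", MAGS, rng.normal(1, 0.3, 18), age=7)
        d1 = classify_cells(a1, a2, n_shuffles=200, seed=3)
        d2 = classify_cells(a1, a2, n_shuffles=200, seed=3)
        pd.testing.assert_frame_equal(d1, d2)

    def test_insufficient_trials_reported_not_dropped(self):
        a1 = _peaks_df("c", "ipsi", [30, 30, 30], [1, 2, 3], age=4)
        a2 = _peaks_df("c", "ipsi", MAGS, np.ones(18), age=7)
        out = classify_cells(a1, a2, directions=("ipsi",), n_shuffles=10, seed=0)
        assert out["category"].iloc[0] == "excluded"
        assert "magnitudes" in out["reason"].iloc[0]

    def test_large_change_at_low_noise_is_detected(self):
        # quadrupling the slope with tight noise must be classified increase
        rng = np.random.default_rng(4)
        y1 = 0.02 * MAGS + rng.normal(0, 0.02, 18)
        y2 = 0.30 * MAGS + rng.normal(0, 0.02, 18)
        out = classify_cells(
            _peaks_df("c", "ipsi", MAGS, y1, 4), _peaks_df("c", "ipsi", MAGS, y2, 7),
            directions=("ipsi",), n_shuffles=500, seed=1,
        )
        assert out["category"].iloc[0] == "increase"

    def test_power_is_monotone_in_true_change(self):
        # detection probability is nondecreasing across a grid of gain rises
        def detect_frac(delta_gain, n_cells=40):
            pop1 = tipm.make_population(
                n_cells, rng=50, gain_ipsi_range=(0.07, 0.07),
                decay_class="plateau", noise_sd=0.2,
            )
            pop2 = tipm.make_population(
                n_cells, rng=50, gain_ipsi_range=(0.07 + delta_gain,) * 2,
                decay_class="plateau", noise_sd=0.2,
            )
            protos = tipm.default_protocols(directions=("ipsi",))
            ps = []
            for seed, pop, age in [(60, pop1, 4), (61, pop2, 7)]:
                cfg = tipm.SimulationConfig(protos, pop, seed=seed, age_dpf=age)
                tr, _ = tipm.simulate_experiment(cfg)
                ps.append(tipm.extract_peaks(tipm.normalize(tr)))
            ch = classify_cells(ps[0], ps[1], directions=("ipsi",),
                                n_shuffles=300, seed=9)
            return (ch["category"] == "increase").mean()

        fracs = [detect_frac(d) for d in (0.0, 0.05, 0.15)]
        assert fracs[0] <= fracs[1] + 0.05 <= fracs[2] + 0.10
        assert fracs[2] > fracs[0]


class TestEarlyTuned:
    def test_flat_cell_is_not_early_tuned(self):
        rng = np.random.default_rng(0)
        y = rng.normal(1.0, 0.2, 18)
        null = single_age_null(MAGS, y, 500, rng=1)
        slope = tipm.sensitivity_slope(MAGS, y).slope
        assert not early_tuned(slope, null)

    def test_strongly_tuned_cell_is_early_tuned(self):
        rng = np.random.default_rng(0)
        y = 0.1 * MAGS + rng.normal(0, 0.1, 18)
        null = single_age_null(MAGS, y, 500, rng=1)
        assert early_tuned(tipm.sensitivity_slope(MAGS, y).slope, null)

    def test_identical_groups_have_zero_ks_statistic(self):
        ch = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(8)], "direction": "contra",
            "delta_slope": [0.1, 0.2, 0.1, 0.2] * 2,
            "early_tuned": [True] * 4 + [False] * 4,
            "category": "no_change",
        })
        out = early_tuned_split(ch)
        assert out["ks_stat"].iloc[0] == pytest.approx(0.0)

    def test_small_group_skipped(self):
        ch = pd.DataFrame({
            "cell_id": ["a", "b", "c"], "direction": "ipsi",
            "delta_slope": [0.1, 0.2, 0.3],
            "early_tuned": [True, False, False], "category": "no_change",
        })
        assert not early_tuned_split(ch)["tested"].iloc[0]

    def test_decrease_only_tuned_group_never_classified_increase(self):
        # construct early-contra-tuned cells whose contra gain only falls
        protos = tipm.default_protocols(directions=("contra",))
        tuned = tipm.make_population(10, rng=70, gain_contra_range=(0.08, 0.1),
                                     noise_sd=0.15, decay_class="plateau")
        tuned2 = [  # gains halved at the second age
            tipm.NeuronGroundTruth(**{**n.to_dict(),
                                      "tonic_gain_contra": n.tonic_gain_contra / 3,
                                      "position_um": n.position_um})
            for n in tuned
        ]
        ps = []
        for seed, pop, age in [(71, tuned, 4), (72, tuned2, 7)]:
            cfg = tipm.SimulationConfig(protos, pop, seed=seed, age_dpf=age)
            ps.append(tipm.extract_peaks(tipm.normalize(
                tipm.simulate_experiment(cfg)[0])))
        ch = classify_cells(ps[0], ps[1], directions=("contra",),
                            n_shuffles=300, seed=2)
        assert (ch["category"] != "increase").all()


class TestChangeCorrelation:
    def test_perfectly_correlated(self):
        d = np.array([0.1, -0.2, 0.3, 0.05])
        rho, p, n = change_correlation(d, d)
        assert rho == pytest.approx(1.0) and n == 4

    def test_anticorrelated(self):
        d = np.array([0.1, -0.2, 0.3, 0.05])
        rho, _, _ = change_correlation(d, -d)
        assert rho == pytest.approx(-1.0)

    def test_too_few_pairs_undefined(self):
        rho, p, n = change_correlation([0.1, 0.2], [0.1, 0.2])
        assert np.isnan(rho) and n == 2

    def test_independent_changes_near_zero(self):
        rng = np.random.default_rng(8)
        rho, _, _ = change_correlation(rng.normal(0, 1, 500), rng.normal(0, 1, 500))
        assert abs(rho) < 0.15
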