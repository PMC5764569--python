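"""Generator contracts: schedule invariants, licking structure, tuning draws."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from striomix import synthgen
from striomix.synthgen import (
    GroundTruthTuning,
    generate_fluorescence,
    generate_licking,
    generate_movie,
    generate_neurons,
    generate_task_schedule,
    outcome_time_s,
)


class TestTaskSchedule:
    def test_type_invariants(self, schedule):
        assert np.allclose(
            schedule["tone_offset_s"] - schedule["tone_onset_s"], 1.5
        )
        rew = schedule[schedule["rewarded"]]
        assert np.allclose(rew["reward_time_s"], rew["tone_offset_s"] + 0.5)
        assert schedule["reward_time_s"][~schedule["rewarded"]].isna().all()
        assert (np.diff(schedule["tone_onset_s"]) > 0).all()
        gaps = schedule["tone_onset_s"].to_numpy()[1:] - outcome_time_s(schedule)[:-1]
        assert ((gaps >= 5.25) & (gaps <= 8.75)).all()

    def test_reward_marginal_matches_programmed_probability(self):
        trials = generate_task_schedule(1000, 0.5, 0.8, 0.2, seed=1)
        high = trials[trials["cue"] == "high"]
        assert abs(high["rewarded"].mean() - 0.8) < 0.04  # 3x binomial SE

    def test_cue_marginal_binomial_consistent(self):
        trials = generate_task_schedule(2000, 0.5, seed=3)
        se = np.sqrt(0.25 / 2000)
        assert abs((trials["cue"] == "high").mean() - 0.5) < 3 * se

    def test_degenerate_probabilities(self):
        trials = generate_task_schedule(10, 0.5, 1.0, 0.0, seed=2)
        assert trials[trials["cue"] == "high"]["rewarded"].all()
        assert not trials[trials["cue"] == "low"]["rewarded"].any()

    def test_seeded_determinism(self):
        a = generate_task_schedule(500, seed=7)
        b = generate_task_schedule(500, seed=7)
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv() == b.to_csv()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_trials": 0},
            {"n_trials": 10, "p_high_cue": 1.5},
            {"n_trials": 10, "iti_range_s": (8.75, 5.25)},
            {"n_trials": 10, "iti_range_s": (-1.0, 2.0)},
        ],
    )
    def test_parameter_errors(self, kwargs):
        with pytest.raises(ValueError):
            generate_task_schedule(**kwargs)


class TestLicking:
    def test_cue_separation_when_learned(self):
        trials = generate_task_schedule(400, seed=31)
        lk = generate_licking(
            trials, learning_level=1.0, anticipatory_rate_high=6.0,
            anticipatory_rate_low=1.0, seed=32,
        )
        counts = {"high": [], "low": []}
        for _, t in trials.iterrows():
            c = np.sum((lk >= t.tone_onset_s) & (lk < t.tone_offset_s + 0.5))
            counts[t.cue].append(c)
        p = stats.mannwhitneyu(
            counts["high"], counts["low"], alternative="greater"
        ).pvalue
        assert p < 0.01

    def test_no_cue_difference_under_null(self):
        rejections = 0
        for seed in range(100):
            trials = generate_task_schedule(100, seed=1000 + seed)
            lk = generate_licking(
                trials, learning_level=0.0, anticipatory_rate_high=3.0,
                anticipatory_rate_low=3.0, seed=2000 + seed,
            )
            counts = {"high": [], "low": []}
            for _, t in trials.iterrows():
                counts[t.cue].append(
                    np.sum((lk >= t.tone_onset_s) & (lk < t.tone_offset_s + 0.5))
                )
            p = stats.mannwhitneyu(
                counts["high"], counts["low"], alternative="two-sided"
            ).pvalue
            rejections += int(p < 0.05)
        assert rejections <= 10  # null calibration: alpha=0.05 holds

    def test_zero_bout_rate_means_no_consummatory_licks(self):
        trials = generate_task_schedule(40, seed=33)
        lk = generate_licking(
            trials, bout_rate=0.0, baseline_rate_hz=0.0, seed=34
        )
        for rt in trials["reward_time_s"].dropna():
            assert not np.any((lk >= rt) & (lk < rt + 3.0))

    def test_refractory_floor(self, licks):
        assert np.all(np.diff(licks) >= 0.05 - 1e-12)
        assert np.all(licks >= 0)

    def test_empty_trials_warns(self):
        empty = generate_task_schedule(1, seed=0).iloc[:0]
        with pytest.warns(UserWarning):
            out = generate_licking(empty, seed=1)
        assert out.size == 0

    def test_consummatory_independent_of_history(self):
        """Bout licking after reward carries no one-back outcome effect."""
        trials = generate_task_schedule(600, seed=35)
        lk = generate_licking(trials, history_effect=0.5, seed=36)
        prev_rew = trials["rewarded"].shift(1).to_numpy()
        post = []
        for i, t in trials.iterrows():
            if t.rewarded and i > 0:
                post.append(
                    (prev_rew[i], np.sum((lk >= t.reward_time_s) & (lk < t.reward_time_s + 2.5)))
                )
        r = [c for p, c in post if p == 1.0]
        u = [c for p, c in post if p == 0.0]
        assert stats.mannwhitneyu(r, u).pvalue > 0.05


class TestNeurons:
    def test_compartment_counts_match_reference_population(self):
        tuning = generate_neurons(2704, striosome_fraction=0.269, seed=41)
        n_strio = sum(t.compartment == "striosome" for t in tuning)
        se = np.sqrt(2704 * 0.269 * 0.731)
        assert abs(n_strio - 727) < 3 * se

    def test_all_silent_mix(self):
        tuning = generate_neurons(
            50, epoch_mix={"cue": 0, "lick": 0, "postlick": 0, "none": 1}, seed=42
        )
        assert all(t.epoch_pref == "none" for t in tuning)

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            generate_neurons(10, epoch_mix={"cue": 0.5, "none": 0.2}, seed=0)

    def test_tuning_validation(self):
        with pytest.raises(ValueError):
            GroundTruthTuning(0, "matrix", False, "sleep", 1, 1, 0, 0, 1)
        with pytest.raises(ValueError):
            GroundTruthTuning(0, "matrix", False, "cue", 1, 1, 1.5, 0, 1)


class TestFluorescence:
    def test_silent_noiseless_neuron_is_flat_baseline(self, schedule, licks):
        tuning = [
            GroundTruthTuning(0, "matrix", False, "none", 0.0, 0.0, 0.0, 0.5, 0.0)
        ]
        fl = generate_fluorescence(
            schedule, licks, tuning, spont_rate_hz=0.0,
            contamination_factor=0.0, ring_noise_sigma=0.0, f0_cell=290.0, seed=43,
        )
        assert np.allclose(fl.f_cell[0], 290.0)

    def test_amplitude_linearity_at_zero_noise(self, schedule, licks):
        """Doubling the event amplitude doubles the event-locked dF/F."""
        def dff_for(gain):
            tuning = [
                GroundTruthTuning(0, "matrix", False, "cue", gain, gain, 0.0, 0.6, 0.0)
            ]
            fl = generate_fluorescence(
                schedule, licks, tuning, spont_rate_hz=0.0,
                contamination_factor=0.0, ring_noise_sigma=0.0, seed=44,
            )
            return 100.0 * (fl.clean[0] - 290.0) / 290.0

        a, b = dff_for(0.4), dff_for(0.8)
        active = a > 1e-9
        assert np.allclose(b[active], 2 * a[active], rtol=1e-6)

    def test_history_gain_scales_postreward_response(self, schedule, licks):
        tuning = [
            GroundTruthTuning(0, "matrix", False, "lick", 1.0, 1.0, 0.5, 0.4, 0.0)
        ]
        fl = generate_fluorescence(
            schedule, licks, tuning, spont_rate_hz=0.0,
            contamination_factor=0.0, ring_noise_sigma=0.0, seed=45,
        )
        from striomix.events import trial_lick_events, window_mean

        ev = trial_lick_events(schedule, licks)
        prev_rew = schedule["rewarded"].shift(1)
        resp = {True: [], False: []}
        for i in range(1, len(schedule)):
            if not ev["included"].iat[i] or pd.isna(prev_rew.iat[i]):
                continue
            t0 = ev["first_reward_lick_s"].iat[i]
            resp[bool(prev_rew.iat[i])].append(
                window_mean(fl.clean[0] - 290.0, 5.0, t0, t0 + 2.0)
            )
        ratio = np.mean(resp[False]) / np.mean(resp[True])
        assert ratio == pytest.approx(1.5, rel=0.12)

    def test_unknown_epoch_rejected(self, schedule, licks):
        bad = GroundTruthTuning(0, "matrix", False, "cue", 1, 1, 0, 0.5, 1.0)
        object.__setattr__(bad, "epoch_pref", "unknown")
        with pytest.raises((ValueError, KeyError)):
            generate_fluorescence(schedule, licks, [bad], seed=0)

    def test_seeded_determinism(self, schedule, licks):
        tuning = generate_neurons(5, seed=46)
        a = generate_fluorescence(schedule, licks, tuning, seed=47)
        b = generate_fluorescence(schedule, licks, tuning, seed=47)
        assert np.array_equal(a.f_cell, b.f_cell)
        assert np.array_equal(a.f_ring, b.f_ring)


@pytest.fixture(scope="module")
def small_fluor(schedule, licks):
    tuning = generate_neurons(6, seed=51)
    fl = generate_fluorescence(schedule, licks, tuning, seed=52)
    return synthgen.FluorescenceData(
        f_cell=fl.f_cell[:, :40], f_ring=fl.f_ring[:, :40],
        clean=fl.clean[:, :40], frame_rate_hz=5.0, tuning=fl.tuning,
    )


class TestMovie:
    def test_zero_jitter_records_zero_shifts(self, small_fluor):
        stack = generate_movie(small_fluor, jitter_amplitude_px=0, seed=53)
        assert np.all(stack.true_shifts == 0)

    def test_masks_disjoint_and_in_bounds(self, small_fluor):
        stack = generate_movie(small_fluor, jitter_amplitude_px=2, seed=54)
        union = np.zeros(stack.frames.shape[1:3], dtype=int)
        for m in stack.roi_masks:
            union += m
        assert union.max() <= 1
        assert (stack.frames >= 0).all()

    def test_overflowing_layout_fails(self, schedule, licks):
        tuning = generate_neurons(80, seed=55)
        fl = generate_fluorescence(schedule, licks, tuning, seed=56)
        small = synthgen.FluorescenceData(
            f_cell=fl.f_cell[:, :10], f_ring=fl.f_ring[:, :10],
            clean=fl.clean[:, :10], frame_rate_hz=5.0, tuning=fl.tuning,
        )
        with pytest.raises(RuntimeError):
            generate_movie(small, field_shape=(24, 24), seed=57)


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_schedule_is_pure_function_of_seed(seed):
    a = generate_task_schedule(20, seed=seed)
    b = generate_task_schedule(20, seed=seed)
    pd.testing.assert_frame_equal(a, b)
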