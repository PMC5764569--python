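"""Alignment, bout delimitation, epoch classification, group fractions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from striomix import synthgen
from striomix.events import (
    align,
    aggregate_region_response,
    classify_epochs,
    classify_population,
    detect_bout_end,
    epoch_fractions,
    fisher_exact_counts,
    peak_sort,
    pooled_baseline,
    trial_lick_events,
    window_mean,
    zscore_aligned,
    zscore_trace,
)

from conftest import make_bump_trace


class TestBoutDetection:
    def test_gap_rule(self):
        licks = 10.0 + np.array([0.1, 0.3, 0.5, 3.0])
        first, last = detect_bout_end(licks, 10.0, 20.0, gap_threshold_s=1.0)
        assert first == pytest.approx(10.1)
        assert last == pytest.approx(10.5)

    def test_no_lick_excluded(self):
        assert detect_bout_end(np.array([1.0]), 10.0, 20.0) is None

    def test_licking_into_next_tone_excluded(self):
        licks = np.arange(10.0, 21.0, 1 / 6)  # continuous 6 Hz
        assert detect_bout_end(licks, 10.0, 17.0) is None

    def test_trial_table_marks_exclusions(self, schedule, licks):
        ev = trial_lick_events(schedule, licks)
        onsets = schedule["tone_onset_s"].to_numpy()
        for i in range(len(schedule) - 1):
            if ev["included"].iat[i]:
                assert ev["last_lick_s"].iat[i] < onsets[i + 1]


class TestAlign:
    def test_constant_trace_gives_constant_rows(self):
        a = align(np.full(500, 3.0), 5.0, np.array([20.0, 40.0]), (-1.0, 3.0))
        assert a.values.shape == (2, 21)
        assert np.allclose(a.values, 3.0)

    def test_window_grid_arithmetic(self):
        a = align(np.zeros(500), 5.0, np.array([50.0]), (-1.0, 3.0))
        assert len(a.time_axis_s) == 21
        assert a.time_axis_s[0] == pytest.approx(-1.0)
        assert a.time_axis_s[-1] == pytest.approx(3.0)
        assert np.allclose(np.diff(a.time_axis_s), 0.2)

    def test_events_outside_session_dropped(self):
        with pytest.warns(UserWarning):
            a = align(np.zeros(50), 5.0, np.array([0.5, np.nan, 500.0]), (-1.0, 3.0))
        assert a.n_trials == 0

    def test_cue_neuron_peak_near_ground_truth(self, cue_neuron_session):
        sess = cue_neuron_session
        fl = sess["fluor"]
        dff = 100 * (fl.clean[0] - 290.0) / 290.0
        a = align(
            dff, 5.0, sess["trials"]["tone_onset_s"].to_numpy(), (-1.0, 3.0)
        )
        peak_t = a.time_axis_s[np.argmax(a.trial_mean())]
        assert abs(peak_t - sess["tuning"][0].peak_offset_s) <= 0.4


class TestZscore:
    def test_baseline_equal_trace_is_zero(self):
        a = align(np.full(500, 5.0), 5.0, np.array([20.0]), (-1.0, 2.0))
        z = zscore_aligned(a, 5.0, 2.0)
        assert np.allclose(z.values, 0.0)

    def test_shifted_response_recovers_shift(self):
        rng = np.random.default_rng(81)
        trace = rng.normal(0, 1, 2000)
        trace[1000:1200] += 2.0
        mean_b, sd_b = pooled_baseline(
            trace, 5.0, np.array([10.0 * (i + 1) for i in range(19)])
        )
        z = zscore_trace(trace, mean_b, sd_b)
        assert np.mean(z[1000:1200]) == pytest.approx(2.0, abs=0.3)

    def test_scale_invariance(self):
        rng = np.random.default_rng(82)
        x = rng.normal(0, 1, 300)
        a = zscore_trace(x, 0.0, 1.0)
        b = zscore_trace(10 * x, 0.0, 10.0)
        assert np.allclose(a, b)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            zscore_trace(np.zeros(10), 0.0, 0.0)


class TestClassification:
    def test_cue_neuron_selective_for_cue(self, cue_neuron_session):
        sess = cue_neuron_session
        fl = sess["fluor"]
        dff = 100 * (fl.f_cell[0] - fl.f_cell[0].mean()) / 290.0
        c = classify_epochs(dff, 5.0, sess["trials"], licks=sess["licks"])
        assert c.cue_mod and not c.lick_mod and not c.postlick_mod
        assert c.selective_epoch == "cue"
        assert c.task_mod

    def test_task_silent_neuron_rarely_flagged(self, schedule, licks):
        rng = np.random.default_rng(83)
        false_positives = 0
        for _ in range(100):
            noise = rng.normal(0, 30, 600)
            c = classify_epochs(noise, 5.0, schedule, licks=licks, alpha=0.01)
            false_positives += int(c.task_mod)
        assert false_positives <= 5

    def test_equal_responses_in_all_epochs_is_multiple(self, schedule, licks):
        ev = trial_lick_events(schedule, licks)
        n = int(np.ceil(synthgen.session_end_s(schedule) * 5))
        times, amps = [], []
        for i in range(len(schedule)):
            times.append(schedule["tone_onset_s"].iat[i] + 0.6)
            amps.append(50.0)
            if ev["included"].iat[i]:
                times.extend(
                    [ev["first_reward_lick_s"].iat[i] + 0.4, ev["last_lick_s"].iat[i] + 0.4]
                )
                amps.extend([50.0, 50.0])
        trace = make_bump_trace(n, 5.0, np.array(times), np.array(amps))
        trace += np.random.default_rng(84).normal(0, 0.5, n)
        c = classify_epochs(trace, 5.0, schedule, lick_events=ev)
        assert c.selective_epoch == "multiple"

    def test_affine_invariance(self, cue_neuron_session):
        """Rank tests make the classification invariant to affine rescaling."""
        sess = cue_neuron_session
        raw = sess["fluor"].f_cell[0]
        c1 = classify_epochs(raw, 5.0, sess["trials"], licks=sess["licks"])
        c2 = classify_epochs(3.7 * raw + 12, 5.0, sess["trials"], licks=sess["licks"])
        assert (c1.cue_mod, c1.lick_mod, c1.postlick_mod) == (
            c2.cue_mod, c2.lick_mod, c2.postlick_mod,
        )
        for k in c1.p_values:
            assert c1.p_values[k] == pytest.approx(c2.p_values[k])

    def test_too_few_trials_indeterminate(self, schedule, licks):
        c = classify_epochs(
            np.zeros(600), 5.0, schedule.iloc[:8], licks=licks, min_trials=10
        )
        assert c.indeterminate

    def test_type_one_error_bounded_under_global_null(self, schedule, licks):
        """Fraction of task-modulated calls under the null <= 1.5 * alpha."""
        rng = np.random.default_rng(85)
        dff = rng.normal(0, 30, size=(200, 600))
        cls = classify_population(dff, 5.0, schedule, licks, alpha=0.01)
        assert cls["task_mod"].mean() <= 1.5 * 0.01 + 1e-12


class TestFractions:
    def test_reference_counts_are_highly_significant(self):
        assert fisher_exact_counts(312, 727, 721, 1977) < 0.005

    def test_identical_groups_p_one(self):
        assert fisher_exact_counts(10, 40, 10, 40) == pytest.approx(1.0)

    def test_small_table_matches_hypergeometric_enumeration(self):
        """Fisher p equals brute-force enumeration over fixed-margin tables."""
        from scipy.stats import hypergeom

        def brute(k1, n1, k2, n2):
            total_k = k1 + k2
            p_obs = hypergeom.pmf(k1, n1 + n2, total_k, n1)
            p = 0.0
            for k in range(max(0, total_k - n2), min(n1, total_k) + 1):
                pk = hypergeom.pmf(k, n1 + n2, total_k, n1)
                if pk <= p_obs * (1 + 1e-9):
                    p += pk
            return p

        assert fisher_exact_counts(3, 4, 1, 4) == pytest.approx(brute(3, 4, 1, 4))
        rng = np.random.default_rng(86)
        for _ in range(30):
            n1, n2 = rng.integers(2, 11, 2)
            k1, k2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            assert fisher_exact_counts(k1, n1, k2, n2) == pytest.approx(
                brute(k1, n1, k2, n2)
            )

    def test_fraction_table_structure(self):
        df = pd.DataFrame(
            {
                "compartment": ["striosome"] * 40 + ["matrix"] * 60,
                "task_mod": [True] * 20 + [False] * 20 + [True] * 20 + [False] * 40,
                "selective_epoch": (["cue"] * 10 + ["lick"] * 10 + ["none"] * 20)
                + (["cue"] * 5 + ["lick"] * 15 + ["none"] * 40),
            }
        )
        frac, contrasts = epoch_fractions(df)
        t = frac.set_index(["compartment", "measure"])
        assert t.loc[("striosome", "task_mod"), "fraction"] == 0.5
        assert t.loc[("matrix", "task_mod"), "fraction"] == pytest.approx(1 / 3)
        assert (t["ci_low"] <= t["fraction"]).all()
        assert (t["ci_high"] >= t["fraction"]).all()
        assert set(contrasts["measure"]) == {
            "task_mod", "selective_cue", "selective_lick", "selective_postlick",
        }

    def test_empty_group_rejected(self):
        df = pd.DataFrame(
            {"compartment": [], "task_mod": [], "selective_epoch": []}
        )
        with pytest.raises(ValueError):
            epoch_fractions(df)


class TestPeakSort:
    def test_ordering_by_peak_time(self):
        mat = np.zeros((3, 5))
        mat[0, 3] = 1.0
        mat[1, 1] = 2.0
        mat[2, 2] = 3.0
        order, norm = peak_sort(mat)
        assert list(order) == [1, 2, 0]
        assert np.allclose(norm.max(axis=1), 1.0)

    def test_flat_rows_unnormalized_and_last(self):
        mat = np.vstack([np.zeros(5), np.eye(5)[2]])
        order, norm = peak_sort(mat)
        assert order[-1] == 0
        assert np.allclose(norm[-1], 0.0)

    def test_spread_offsets_give_monotone_ridge(self):
        rng = np.random.default_rng(87)
        peaks = np.sort(rng.integers(0, 40, 25))
        mat = np.array(
            [np.exp(-0.5 * ((np.arange(40) - p) / 2.0) ** 2) for p in peaks]
        )
        order, norm = peak_sort(mat[rng.permutation(25)])
        ridge = np.argmax(norm, axis=1)
        assert np.all(np.diff(ridge) >= 0)


class TestRegionAggregate:
    def _sessions(self, n, gain_ratio, seed, noise=25.0):
        out = []
        for s in range(n):
            trials = synthgen.generate_task_schedule(40, seed=seed + s)
            licks = synthgen.generate_licking(trials, seed=seed + 500 + s)
            regions = synthgen.generate_region_traces(
                trials, licks,
                cue_gain={
                    "striosome": (0.2 * gain_ratio, 0.12 * gain_ratio),
                    "matrix": (0.2, 0.12),
                },
                noise_sigma=noise,
                seed=seed + 1000 + s,
            )
            out.append(
                {"session_id": f"s{s}", "trials": trials, "frame_rate_hz": 5.0, **regions}
            )
        return out

    def test_identical_regions_have_no_compartment_effect(self):
        sessions = self._sessions(6, 1.0, seed=880)
        for s in sessions:
            s["matrix"] = s["striosome"].copy()
        res = aggregate_region_response(sessions)
        wide = res["table"].pivot_table(
            index="session_id", columns="compartment", values="response"
        )
        assert np.allclose(wide["striosome"], wide["matrix"])

    def test_compartment_gain_detected(self):
        res = aggregate_region_response(self._sessions(30, 1.5, seed=890))
        assert res["p_compartment"] < 0.01
        m = res["table"].groupby("compartment")["response"].mean()
        assert m["striosome"] > m["matrix"]

    def test_cue_effect_detected(self):
        res = aggregate_region_response(self._sessions(20, 1.0, seed=900))
        assert res["p_cue"] < 0.01
        m = res["table"].groupby("cue")["response"].mean()
        assert m["high"] > m["low"]

    def test_unpaired_session_rejected(self):
        sessions = self._sessions(3, 1.0, seed=910)
        del sessions[1]["matrix"]
        with pytest.raises(ValueError):
            aggregate_region_response(sessions)
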