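"""Extraction: registration, neuropil subtraction, baseline mode, dF/F."""

import numpy as np
import pytest
from scipy.stats import gaussian_kde

from striomix import synthgen
from striomix.extract import (
    assign_compartment,
    compute_dff,
    estimate_baseline_mode,
    extract_roi_fluorescence,
    register_translation,
    resample_traces,
    subtract_neuropil_traces,
    traces_to_dff,
)
from striomix.synthgen import FluorescenceData, generate_fluorescence, generate_movie, generate_neurons


@pytest.fixture(scope="module")
def jittered_stack(schedule, licks):
    tuning = generate_neurons(8, seed=61)
    fl = generate_fluorescence(schedule, licks, tuning, seed=62)
    small = FluorescenceData(
        f_cell=fl.f_cell[:, :50], f_ring=fl.f_ring[:, :50],
        clean=fl.clean[:, :50], frame_rate_hz=5.0, tuning=fl.tuning,
    )
    return generate_movie(small, field_shape=(48, 48), jitter_amplitude_px=4, seed=63)


class TestRegistration:
    def test_known_shifts_recovered_exactly(self, jittered_stack):
        shifts, _ = register_translation(jittered_stack)
        assert np.array_equal(shifts, jittered_stack.true_shifts)

    def test_zero_jitter_gives_zero_shifts(self, schedule, licks):
        tuning = generate_neurons(5, seed=64)
        fl = generate_fluorescence(schedule, licks, tuning, seed=65)
        small = FluorescenceData(
            f_cell=fl.f_cell[:, :30], f_ring=fl.f_ring[:, :30],
            clean=fl.clean[:, :30], frame_rate_hz=5.0, tuning=fl.tuning,
        )
        stack = generate_movie(small, field_shape=(48, 48), jitter_amplitude_px=0, seed=66)
        shifts, _ = register_translation(stack)
        assert np.all(shifts == 0)

    def test_green_channel_registration_agrees(self, jittered_stack):
        """Structural- vs functional-channel registration: same shifts."""
        shifts_red, _ = register_translation(jittered_stack)
        swapped = synthgen.MovieStack(
            frames=jittered_stack.frames[..., ::-1].copy(),
            frame_rate_hz=jittered_stack.frame_rate_hz,
            roi_masks=jittered_stack.roi_masks,
            striosome_neuropil_mask=jittered_stack.striosome_neuropil_mask,
            true_shifts=jittered_stack.true_shifts,
        )
        shifts_green, _ = register_translation(swapped)
        agreement = np.mean(np.all(shifts_green == shifts_red, axis=1))
        assert agreement >= 0.99

    def test_flat_frame_warns_and_returns_zero(self):
        frames = np.zeros((2, 16, 16, 2), dtype=np.float32)
        frames[0, :, :, 1] = np.random.default_rng(0).random((16, 16))
        stack = synthgen.MovieStack(
            frames=frames, frame_rate_hz=5.0, roi_masks=[],
            striosome_neuropil_mask=np.zeros((16, 16), bool),
            true_shifts=np.zeros((2, 2), int),
        )
        with pytest.warns(UserWarning):
            shifts, _ = register_translation(stack)
        assert tuple(shifts[1]) == (0, 0)


class TestRoiExtraction:
    def _uniform_stack(self):
        img = np.full((20, 20), 50.0)
        mask = np.zeros((20, 20), bool)
        mask[8:12, 8:12] = True
        img[mask] = 100.0
        return img[None, :, :], mask

    def test_annulus_subtraction_arithmetic(self):
        green, mask = self._uniform_stack()
        trace = extract_roi_fluorescence(green, [mask])
        assert trace[0, 0] == pytest.approx(100 - 0.7 * 50)

    def test_zero_factor_is_plain_roi_mean(self):
        green, mask = self._uniform_stack()
        trace = extract_roi_fluorescence(green, [mask], neuropil_factor=0.0)
        assert trace[0, 0] == pytest.approx(100.0)

    def test_empty_ring_falls_back_with_warning(self):
        green = np.full((1, 10, 10), 80.0)
        mask = np.ones((10, 10), bool)
        with pytest.warns(UserWarning):
            trace = extract_roi_fluorescence(green, [mask])
        assert trace[0, 0] == pytest.approx(80.0)

    def test_subtraction_improves_signal_recovery(self):
        """With a soma contaminated by an independent neuropil process,
        0.7x ring subtraction raises the correlation with the true signal."""
        from scipy.ndimage import gaussian_filter1d

        rng = np.random.default_rng(67)
        n = 3000
        truth = np.clip(gaussian_filter1d(rng.normal(0, 1, n), 8), 0, None) * 60
        npil = np.clip(gaussian_filter1d(rng.normal(0, 1, n), 8), 0, None) * 80
        f_cell = 290 + truth + 0.7 * npil + rng.normal(0, 5, n)
        f_ring = 200 + npil + rng.normal(0, 5, n)
        raw_r = np.corrcoef(f_cell, truth)[0, 1]
        sub_r = np.corrcoef(subtract_neuropil_traces(f_cell, f_ring), truth)[0, 1]
        assert sub_r > raw_r


class TestBaselineMode:
    def test_constant_trace(self):
        assert estimate_baseline_mode(np.full(200, 100.0)) == 100.0

    def test_transient_mixture_mode_near_baseline(self):
        rng = np.random.default_rng(70)
        trace = np.concatenate(
            [rng.normal(100, 2, 1600), rng.normal(160, 10, 400)]
        )
        assert 98 <= estimate_baseline_mode(trace) <= 102

    def test_bimodal_taller_mode_wins(self):
        rng = np.random.default_rng(71)
        trace = np.concatenate([rng.normal(50, 2, 1500), rng.normal(120, 2, 500)])
        f0 = estimate_baseline_mode(trace)
        assert abs(f0 - 50) < 5
        assert abs(f0 - trace.mean()) > 10  # not the mean

    def test_matches_direct_kde_evaluation(self):
        """Binned evaluation equals argmax of the direct Gaussian KDE."""
        rng = np.random.default_rng(72)
        for _ in range(10):
            trace = np.concatenate(
                [rng.normal(100, 3, 800), rng.exponential(40, 200) + 100]
            )
            grid = np.linspace(trace.min(), trace.max(), 512)
            direct = float(
                grid[np.argmax(gaussian_kde(trace, bw_method="silverman")(grid))]
            )
            step = (trace.max() - trace.min()) / 511
            assert abs(estimate_baseline_mode(trace) - direct) <= step + 1e-9

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            estimate_baseline_mode(np.array([1.0, np.nan, 2.0]))


class TestDff:
    def test_arithmetic(self):
        assert compute_dff(np.array([120.0]), 100.0)[0] == pytest.approx(20.0)
        assert compute_dff(np.array([100.0]), 100.0)[0] == 0.0

    def test_nonpositive_f0_rejected(self):
        with pytest.raises(ValueError):
            compute_dff(np.array([1.0]), 0.0)

    def test_baseline_scale_matches_realistic_statistics(self, schedule, licks):
        """Default generator: baseline dF/F mean ~10% and SD ~35-40%."""
        from striomix.events import window_samples

        tuning = generate_neurons(40, seed=73)
        fl = generate_fluorescence(schedule, licks, tuning, seed=74)
        d = traces_to_dff(fl.f_cell, fl.f_ring, 5.0)
        onsets = schedule["tone_onset_s"].to_numpy()
        means, sds = [], []
        for j in range(d.n_neurons):
            seg = np.concatenate(
                [window_samples(d.dff[j], 5.0, t - 1.0, t) for t in onsets]
            )
            means.append(seg.mean())
            sds.append(seg.std())
        assert 4 < np.mean(means) < 25
        assert 25 < np.mean(sds) < 55


class TestResample:
    def test_constant_preserved(self):
        out = resample_traces(np.full(200, 7.0), 20.0, 5.0)
        assert len(out) == 50
        assert np.allclose(out, 7.0)

    def test_nyquist_safe_tone_amplitude(self):
        t = np.arange(0, 60, 0.1)  # 10 Hz
        x = np.sin(2 * np.pi * 0.5 * t)
        y = resample_traces(x, 10.0, 5.0)[10:-10]
        ty = np.arange(y.size) / 5.0
        # amplitude by projection onto the tone (robust to sampling phase)
        amp = 2 * np.abs(np.mean(y * np.exp(-2j * np.pi * 0.5 * (ty + 2.0))))
        assert abs(amp - 1.0) < 0.02

    def test_identity_at_native_rate(self):
        x = np.random.default_rng(75).random(100)
        assert np.array_equal(resample_traces(x, 5.0, 5.0), x)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample_traces(np.zeros(10), 2.0, 5.0)


class TestCompartmentAssignment:
    def test_label_logic(self):
        mask = np.zeros((10, 10), bool)
        mask[:, :5] = True
        cents = np.array([[2.0, 2.0], [2.0, 8.0], [8.0, 8.0]])
        flags = np.array([False, True, False])
        out = assign_compartment(cents, mask, flags)
        assert list(out["compartment"]) == ["striosome", "striosome", "matrix"]
        # labeled cell outside the dense zone: striosomal but flagged outside
        assert not out["in_striosomal_neuropil"].iloc[1]

    def test_empty_mask_no_flags_all_matrix(self):
        mask = np.zeros((10, 10), bool)
        out = assign_compartment(
            np.array([[1.0, 1.0], [5.0, 5.0]]), mask, [False, False]
        )
        assert (out["compartment"] == "matrix").all()

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            assign_compartment(
                np.array([[50.0, 1.0]]), np.zeros((10, 10), bool), [False]
            )
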