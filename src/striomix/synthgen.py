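"""Synthetic two-photon conditioning experiments.

Generates the full stack of artifacts the analysis pipeline consumes:
trial schedules for a two-tone probabilistic reward task, lick trains with
learning- and history-dependent anticipatory licking, ground-truth neural
tuning with striosome/matrix compartment labels, GCaMP6s-like fluorescence
traces with neuropil contamination, and (optionally) two-channel movies
with rigid jitter.

Task structure emulated
-----------------------
Two auditory cues (1.5 s) predict water reward with 80% / 20% probability.
Reward, when delivered, arrives 0.5 s after tone offset.  The gap from the
outcome time of one trial to the next tone onset is drawn uniformly from
[5.25, 8.75] s.  Anticipatory licking during the tone + delay separates by
cue as learning progresses and carries a one-back outcome effect;
consummatory licking after reward does not depend on the previous outcome.

Every generator is a pure function of its parameters and an integer seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TONE_DURATION_S",
    "REWARD_DELAY_S",
    "LICK_REFRACTORY_S",
    "GroundTruthTuning",
    "FluorescenceData",
    "MovieStack",
    "generate_task_schedule",
    "generate_licking",
    "generate_neurons",
    "generate_fluorescence",
    "generate_region_traces",
    "generate_movie",
    "session_end_s",
    "calcium_kernel",
    "DEFAULT_EPOCH_MIX",
    "DEFAULT_COMPARTMENT_PROFILE",
]

TONE_DURATION_S = 1.5
REWARD_DELAY_S = 0.5
LICK_REFRACTORY_S = 0.05  # physiological refractory floor between licks

#: Epoch-preference mix for the default population: roughly 38% of neurons
#: are task-responsive, and of those ~57% prefer the post-reward licking
#: period, ~17% the cue, ~11% the post-licking period.
DEFAULT_EPOCH_MIX: dict[str, float] = {
    "cue": 0.065,
    "lick": 0.218,
    "postlick": 0.042,
    "none": 0.675,
}

#: (cue-gain multiplier, history gain) per compartment.  Striosomal neurons
#: respond about twice as strongly to reward-predicting cues; matrix neurons
#: carry a stronger one-back reward-history modulation of their post-reward
#: responses.
DEFAULT_COMPARTMENT_PROFILE: dict[str, tuple[float, float]] = {
    "striosome": (2.0, 0.1),
    "matrix": (1.0, 0.4),
}

_EPOCHS = ("cue", "lick", "postlick", "none")


# ---------------------------------------------------------------------------
# task schedule
# ---------------------------------------------------------------------------

def generate_task_schedule(
    n_trials: int,
    p_high_cue: float = 0.5,
    p_reward_high: float = 0.8,
    p_reward_low: float = 0.2,
    iti_range_s: tuple[float, float] = (5.25, 8.75),
    seed: int = 0,
    session_id: str = "s0",
    t_first_tone_s: float = 5.0,
) -> pd.DataFrame:
    """Draw a trial schedule for the two-tone probabilistic reward task.

    Cue identity and reward delivery are independent Bernoulli draws per
    trial.  The inter-trial interval (outcome time to next tone onset) is
    uniform on ``iti_range_s``.  The outcome time of a trial is its reward
    time when rewarded and tone offset + 0.5 s otherwise.

    Returns a DataFrame with one row per trial and columns ``trial_id``,
    ``cue`` ("high"/"low"), ``tone_onset_s``, ``tone_offset_s``,
    ``reward_time_s`` (NaN on unrewarded trials), ``rewarded``,
    ``session_id``.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    for name, p in (
        ("p_high_cue", p_high_cue),
        ("p_reward_high", p_reward_high),
        ("p_reward_low", p_reward_low),
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    lo, hi = float(iti_range_s[0]), float(iti_range_s[1])
    if not (0.0 < lo <= hi):
        raise ValueError(f"iti_range_s must be a positive interval, got {iti_range_s}")

    rng = np.random.default_rng(seed)
    is_high = rng.random(n_trials) < p_high_cue
    p_rew = np.where(is_high, p_reward_high, p_reward_low)
    rewarded = rng.random(n_trials) < p_rew
    itis = rng.uniform(lo, hi, size=n_trials)  # gap following each trial

    onsets = np.empty(n_trials)
    onsets[0] = t_first_tone_s
    outcome_offset = TONE_DURATION_S + REWARD_DELAY_S
    for i in range(1, n_trials):
        onsets[i] = onsets[i - 1] + outcome_offset + itis[i - 1]

    offsets = onsets + TONE_DURATION_S
    reward_times = np.where(rewarded, offsets + REWARD_DELAY_S, np.nan)
    return pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "cue": np.where(is_high, "high", "low"),
            "tone_onset_s": onsets,
            "tone_offset_s": offsets,
            "reward_time_s": reward_times,
            "rewarded": rewarded,
            "session_id": session_id,
        }
    )


def outcome_time_s(trials: pd.DataFrame) -> np.ndarray:
    """Per-trial outcome time: reward time, or tone offset + 0.5 s unrewarded."""
    return np.where(
        trials["rewarded"].to_numpy(),
        trials["reward_time_s"].to_numpy(),
        trials["tone_offset_s"].to_numpy() + REWARD_DELAY_S,
    )


def session_end_s(trials: pd.DataFrame, pad_s: float = 8.75) -> float:
    """Session duration in seconds (last outcome plus a final ITI pad)."""
    if len(trials) == 0:
        return 0.0
    return float(outcome_time_s(trials)[-1] + pad_s)


# ---------------------------------------------------------------------------
# licking
# ---------------------------------------------------------------------------

def generate_licking(
    trials: pd.DataFrame,
    learning_level: float = 1.0,
    anticipatory_rate_high: float = 6.0,
    anticipatory_rate_low: float = 1.5,
    history_effect: float = 0.3,
    bout_rate: float = 7.0,
    bout_duration_s: float = 2.5,
    baseline_rate_hz: float = 0.2,
    seed: int = 0,
) -> np.ndarray:
    """Draw a lick train for one session as a sorted array of times (s).

    Anticipatory licks are an inhomogeneous Poisson process during
    [tone onset, tone offset + 0.5 s].  ``learning_level`` in [0, 1] scales
    the high/low cue rate separation around their common mean; the rate of
    trial *t* is additionally multiplied by
    ``1 + history_effect * 1[trial t-1 rewarded]``.  Consummatory licking
    after reward is a Poisson bout at ``bout_rate`` for ``bout_duration_s``
    with no history dependence.  A low spontaneous rate runs throughout the
    session.  Inter-lick intervals below 50 ms are pruned.
    """
    for name, v in (
        ("anticipatory_rate_high", anticipatory_rate_high),
        ("anticipatory_rate_low", anticipatory_rate_low),
        ("bout_rate", bout_rate),
        ("baseline_rate_hz", baseline_rate_hz),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if len(trials) == 0:
        warnings.warn("empty trial table: returning empty lick train", stacklevel=2)
        return np.empty(0)

    rng = np.random.default_rng(seed)
    mean_rate = 0.5 * (anticipatory_rate_high + anticipatory_rate_low)
    r_high = mean_rate + learning_level * (anticipatory_rate_high - mean_rate)
    r_low = mean_rate + learning_level * (anticipatory_rate_low - mean_rate)

    rewarded = trials["rewarded"].to_numpy()
    onsets = trials["tone_onset_s"].to_numpy()
    offsets = trials["tone_offset_s"].to_numpy()
    reward_times = trials["reward_time_s"].to_numpy()

    licks: list[np.ndarray] = []
    for i in range(len(trials)):
        rate = r_high if trials["cue"].iat[i] == "high" else r_low
        if i > 0 and rewarded[i - 1]:
            rate *= 1.0 + history_effect
        t0, t1 = onsets[i], offsets[i] + REWARD_DELAY_S
        n = rng.poisson(max(rate, 0.0) * (t1 - t0))
        if n:
            licks.append(rng.uniform(t0, t1, size=n))
        if rewarded[i] and bout_rate > 0:
            nb = rng.poisson(bout_rate * bout_duration_s)
            if nb:
                licks.append(
                    rng.uniform(reward_times[i], reward_times[i] + bout_duration_s, size=nb)
                )

    t_end = session_end_s(trials)
    nbl = rng.poisson(baseline_rate_hz * t_end)
    if nbl:
        licks.append(rng.uniform(0.0, t_end, size=nbl))

    if not licks:
        return np.empty(0)
    out = np.sort(np.concatenate(licks))
    return _enforce_refractory(out, LICK_REFRACTORY_S)


def _enforce_refractory(times: np.ndarray, floor_s: float) -> np.ndarray:
    """Greedily drop licks that follow the previous kept lick by < floor_s."""
    if times.size == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= floor_s:
            kept.append(t)
    return np.asarray(kept)


# ---------------------------------------------------------------------------
# ground-truth tuning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthTuning:
    """True tuning of one synthetic neuron (the recovery target).

    ``cue_gain_high`` / ``cue_gain_low`` are event amplitudes expressed as a
    fraction of baseline fluorescence (0.2 = a 20% dF/F transient).  For
    lick- and postlick-preferring neurons ``cue_gain_high`` serves as the
    generic event amplitude.  ``history_gain`` h multiplies the post-reward
    (lick-epoch) response by ``1 + h * 1[previous trial unrewarded]``.
    """

    neuron_id: int
    compartment: str  # "striosome" | "matrix"
    tdtomato: bool
    epoch_pref: str  # "cue" | "lick" | "postlick" | "none"
    cue_gain_high: float
    cue_gain_low: float
    history_gain: float
    peak_offset_s: float
    noise_sigma: float  # fluorescence units

    def __post_init__(self) -> None:
        if self.epoch_pref not in _EPOCHS:
            raise ValueError(f"unknown epoch_pref {self.epoch_pref!r}")
        if self.cue_gain_high < 0:
            raise ValueError("cue_gain_high must be >= 0")
        if abs(self.history_gain) > 1:
            raise ValueError("|history_gain| must be <= 1")


def tuning_frame(tuning: Sequence[GroundTruthTuning]) -> pd.DataFrame:
    """Tabulate a tuning list as a DataFrame (one row per neuron)."""
    return pd.DataFrame([t.__dict__ for t in tuning])


def generate_neurons(
    n_neurons: int,
    striosome_fraction: float = 0.269,
    epoch_mix: Mapping[str, float] | None = None,
    compartment_gain_profile: Mapping[str, tuple[float, float]] | None = None,
    tdtomato_fraction: float = 0.15,
    tdtomato_matrix_fraction: float = 0.01,
    amplitude_median: float = 0.25,
    amplitude_sigma_ln: float = 0.7,
    epoch_amplitude_scale: Mapping[str, float] | None = None,
    cue_low_ratio: float = 0.6,
    peak_offset_ranges: Mapping[str, tuple[float, float]] | None = None,
    noise_sigma: float = 65.0,
    seed: int = 0,
) -> list[GroundTruthTuning]:
    """Sample a population of ground-truth-tuned neurons.

    Compartment labels are Bernoulli(``striosome_fraction``); about 15% of
    striosomal neurons (and ~1% of matrix neurons) carry the red structural
    label directly, matching the sparse birthdate tagging.  Epoch preference
    follows ``epoch_mix``.  Base event amplitudes are lognormal
    (median ``amplitude_median``, log-SD ``amplitude_sigma_ln``) and are
    multiplied by the compartment's cue-gain multiplier and by the
    epoch-specific scale in ``epoch_amplitude_scale`` (cue responses are
    typically weaker than post-reward consumption responses); the history
    gain is the compartment's profile value.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    mix = dict(DEFAULT_EPOCH_MIX if epoch_mix is None else epoch_mix)
    probs = np.array([mix.get(e, 0.0) for e in _EPOCHS], dtype=float)
    if (probs < 0).any() or not np.isclose(probs.sum(), 1.0, atol=1e-8):
        raise ValueError(f"epoch_mix must be a distribution over {_EPOCHS}, got {mix}")
    probs = probs / probs.sum()
    profile = dict(
        DEFAULT_COMPARTMENT_PROFILE
        if compartment_gain_profile is None
        else compartment_gain_profile
    )
    offsets = dict(peak_offset_ranges or {})
    offsets.setdefault("cue", (0.2, 1.8))
    offsets.setdefault("lick", (0.2, 2.5))
    offsets.setdefault("postlick", (0.0, 1.0))
    offsets.setdefault("none", (0.0, 0.0))

    rng = np.random.default_rng(seed)
    out: list[GroundTruthTuning] = []
    for i in range(n_neurons):
        comp = "striosome" if rng.random() < striosome_fraction else "matrix"
        td_frac = tdtomato_fraction if comp == "striosome" else tdtomato_matrix_fraction
        tdtomato = bool(rng.random() < td_frac)
        epoch = _EPOCHS[rng.choice(len(_EPOCHS), p=probs)]
        cue_mult, hist_gain = profile[comp]
        base = float(rng.lognormal(np.log(amplitude_median), amplitude_sigma_ln))
        scale = dict(epoch_amplitude_scale or {}).get(epoch, 1.0)
        gain_high = base * scale * (cue_mult if epoch == "cue" else 1.0)
        lo, hi = offsets[epoch]
        out.append(
            GroundTruthTuning(
                neuron_id=i,
                compartment=comp,
                tdtomato=tdtomato,
                epoch_pref=epoch,
                cue_gain_high=gain_high,
                cue_gain_low=gain_high * cue_low_ratio,
                history_gain=float(hist_gain) if epoch == "lick" else 0.0,
                peak_offset_s=float(rng.uniform(lo, hi)),
                noise_sigma=noise_sigma,
            )
        )
    return out


# ---------------------------------------------------------------------------
# fluorescence
# ---------------------------------------------------------------------------

def calcium_kernel(
    rise_s: float, decay_s: float, frame_rate_hz: float, length_s: float = 12.0
) -> np.ndarray:
    """Difference-of-exponentials indicator kernel, peak-normalized to 1.

    Defaults elsewhere (rise 0.2 s, decay 1.5 s) are literature-typical for
    the slow GCaMP6s indicator.
    """
    if not rise_s < decay_s:
        raise ValueError(f"rise_s must be < decay_s, got {rise_s} >= {decay_s}")
    t = np.arange(0.0, length_s, 1.0 / frame_rate_hz)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate kernel")
    return k / peak


@dataclass
class FluorescenceData:
    """Raw traces for one session: per-neuron somatic + neuropil-ring pairs.

    ``f_cell`` rows contain the contaminated somatic signal (intrinsic
    baseline + transients + a share of the shared neuropil signal);
    ``f_ring`` rows contain the matching annulus signal.  ``clean`` holds
    the noise- and contamination-free somatic trace for oracle tests.
    """

    f_cell: np.ndarray  # (n_neurons, T)
    f_ring: np.ndarray  # (n_neurons, T)
    clean: np.ndarray  # (n_neurons, T)
    frame_rate_hz: float
    tuning: list[GroundTruthTuning] = field(default_factory=list)

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.f_cell.shape[1]) / self.frame_rate_hz


def _kernel_peak_lag_s(rise_s: float, decay_s: float) -> float:
    """Time from impulse to kernel peak for the difference of exponentials."""
    return float(
        np.log(decay_s / rise_s) * (rise_s * decay_s) / (decay_s - rise_s)
    )


def _event_times_and_amps(
    tuning: GroundTruthTuning,
    trials: pd.DataFrame,
    lick_events: pd.DataFrame,
    peak_lag_s: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-locked impulse times and amplitudes for one neuron.

    Impulses are placed ``peak_lag_s`` before the intended peak time so the
    rendered transient peaks at anchor + ``peak_offset_s``.
    """
    if tuning.epoch_pref not in _EPOCHS:
        raise ValueError(f"tuning references unknown epoch {tuning.epoch_pref!r}")
    times: list[float] = []
    amps: list[float] = []
    rewarded = trials["rewarded"].to_numpy()
    if tuning.epoch_pref == "cue":
        for i in range(len(trials)):
            amp = (
                tuning.cue_gain_high
                if trials["cue"].iat[i] == "high"
                else tuning.cue_gain_low
            )
            times.append(
                trials["tone_onset_s"].iat[i] + tuning.peak_offset_s - peak_lag_s
            )
            amps.append(amp)
    elif tuning.epoch_pref in ("lick", "postlick"):
        anchor = "first_reward_lick_s" if tuning.epoch_pref == "lick" else "last_lick_s"
        for i in range(len(trials)):
            if not rewarded[i]:
                continue
            t_anchor = lick_events[anchor].iat[i]
            if not np.isfinite(t_anchor):
                continue
            amp = tuning.cue_gain_high
            if tuning.epoch_pref == "lick" and i > 0 and not rewarded[i - 1]:
                amp *= 1.0 + tuning.history_gain
            times.append(t_anchor + tuning.peak_offset_s - peak_lag_s)
            amps.append(amp)
    return np.asarray(times), np.asarray(amps)


def generate_fluorescence(
    trials: pd.DataFrame,
    licks: np.ndarray,
    tuning: Sequence[GroundTruthTuning],
    kernel: tuple[float, float] = (0.2, 1.5),
    f0_cell: float = 290.0,
    f0_ring: float = 200.0,
    neuropil_trace_gain: float = 0.3,
    contamination_factor: float = 0.7,
    frame_rate_hz: float = 5.0,
    spont_rate_hz: float = 0.18,
    spont_amp_mean: float = 0.5,
    ring_noise_sigma: float = 15.0,
    seed: int = 0,
) -> FluorescenceData:
    """Render raw somatic and neuropil-ring fluorescence traces.

    Each neuron's transients are an impulse train of trial-locked events
    (amplitude = tuning gain x ``f0_cell``) plus spontaneous events at
    ``spont_rate_hz`` with exponential amplitudes, convolved with a
    difference-of-exponentials kernel.  A single shared neuropil signal
    (the population-mean transient signal scaled by ``neuropil_trace_gain``)
    contaminates every somatic trace with weight ``contamination_factor``
    and forms the ring traces, so the standard 0.7x annulus subtraction
    removes it.  Gaussian noise is added per trace.
    """
    rise_s, decay_s = kernel
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be > 0")
    from .events import trial_lick_events  # events takes only DataFrames; no cycle

    rng = np.random.default_rng(seed)
    t_end = session_end_s(trials)
    n_frames = int(np.ceil(t_end * frame_rate_hz))
    k = calcium_kernel(rise_s, decay_s, frame_rate_hz)
    lick_events = trial_lick_events(trials, licks)

    peak_lag = _kernel_peak_lag_s(rise_s, decay_s)
    n = len(tuning)
    clean = np.zeros((n, n_frames))
    for j, tun in enumerate(tuning):
        impulses = np.zeros(n_frames)
        times, amps = _event_times_and_amps(tun, trials, lick_events, peak_lag)
        if spont_rate_hz > 0:
            n_sp = rng.poisson(spont_rate_hz * t_end)
            sp_t = rng.uniform(0.0, t_end, size=n_sp)
            sp_a = rng.exponential(spont_amp_mean, size=n_sp)
            times = np.concatenate([times, sp_t])
            amps = np.concatenate([amps, sp_a])
        if times.size:
            idx = np.round(times * frame_rate_hz).astype(int)
            ok = (idx >= 0) & (idx < n_frames)
            np.add.at(impulses, idx[ok], amps[ok])
        clean[j] = f0_cell * np.convolve(impulses, k)[:n_frames]

    shared = neuropil_trace_gain * clean.mean(axis=0)  # shared neuropil signal
    f_ring = (
        f0_ring
        + shared
        + rng.normal(0.0, ring_noise_sigma, size=(n, n_frames))
    )
    noise = np.stack(
        [rng.normal(0.0, tun.noise_sigma, size=n_frames) for tun in tuning]
    )
    f_cell = (
        f0_cell
        + contamination_factor * f0_ring
        + clean
        + contamination_factor * shared
        + noise
    )
    return FluorescenceData(
        f_cell=f_cell,
        f_ring=f_ring,
        clean=f0_cell + clean,
        frame_rate_hz=frame_rate_hz,
        tuning=list(tuning),
    )


def generate_region_traces(
    trials: pd.DataFrame,
    licks: np.ndarray,
    cue_gain: Mapping[str, tuple[float, float]] | None = None,
    reward_gain: Mapping[str, float] | None = None,
    f0: float = 300.0,
    kernel: tuple[float, float] = (0.2, 1.5),
    frame_rate_hz: float = 5.0,
    noise_sigma: float = 25.0,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Aggregate neuropil fluorescence for one striosome/matrix region pair.

    ``cue_gain`` maps compartment -> (high-cue, low-cue) response amplitude
    (fraction of baseline); ``reward_gain`` maps compartment -> post-reward
    amplitude.  Both compartments see the same trials and licks, mirroring
    paired region ROIs drawn in the same field of view.
    """
    cue_gain = dict(
        cue_gain
        if cue_gain is not None
        else {"striosome": (0.30, 0.18), "matrix": (0.15, 0.09)}
    )
    reward_gain = dict(
        reward_gain if reward_gain is not None else {"striosome": 0.35, "matrix": 0.35}
    )
    rng = np.random.default_rng(seed)
    t_end = session_end_s(trials)
    n_frames = int(np.ceil(t_end * frame_rate_hz))
    k = calcium_kernel(*kernel, frame_rate_hz)
    out: dict[str, np.ndarray] = {}
    for comp in ("striosome", "matrix"):
        impulses = np.zeros(n_frames)
        gh, gl = cue_gain[comp]
        for i in range(len(trials)):
            amp = gh if trials["cue"].iat[i] == "high" else gl
            idx = int(round((trials["tone_onset_s"].iat[i] + 0.4) * frame_rate_hz))
            if 0 <= idx < n_frames:
                impulses[idx] += amp
            if trials["rewarded"].iat[i]:
                ridx = int(
                    round((trials["reward_time_s"].iat[i] + 0.8) * frame_rate_hz)
                )
                if 0 <= ridx < n_frames:
                    impulses[ridx] += reward_gain[comp]
        sig = f0 * (1.0 + np.convolve(impulses, k)[:n_frames])
        out[comp] = sig + rng.normal(0.0, noise_sigma, size=n_frames)
    return out


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------

@dataclass
class MovieStack:
    """Two-channel movie: channel 0 functional (green), channel 1 structural (red)."""

    frames: np.ndarray  # (T, H, W, 2), float32, >= 0
    frame_rate_hz: float
    roi_masks: list[np.ndarray]  # per-neuron boolean (H, W)
    striosome_neuropil_mask: np.ndarray  # boolean (H, W)
    true_shifts: np.ndarray  # (T, 2) int, (dy, dx) applied per frame

    def __post_init__(self) -> None:
        h, w = self.frames.shape[1:3]
        for m in self.roi_masks:
            if m.shape != (h, w):
                raise ValueError("roi mask shape mismatch")
        union = np.zeros((h, w), dtype=int)
        for m in self.roi_masks:
            union += m.astype(int)
        if (union > 1).any():
            raise ValueError("roi masks must be pairwise disjoint")
        if (self.frames < 0).any():
            raise ValueError("intensities must be >= 0")


def generate_movie(
    fluor: FluorescenceData,
    field_shape: tuple[int, int] = (64, 64),
    roi_radius_px: int = 3,
    jitter_amplitude_px: int = 0,
    neuropil_level: float = 40.0,
    pixel_noise_sigma: float = 1.0,
    seed: int = 0,
    max_placement_tries: int = 200,
) -> MovieStack:
    """Render per-neuron traces into a jittered two-channel movie.

    Striosomal neurons are placed inside a dense tdTomato neuropil zone
    occupying the left part of the field; matrix neurons outside it.  The
    green channel carries each neuron's clean somatic trace inside its mask
    plus a diffuse neuropil level; the red channel is dominated by the
    structural signal (dense in the striosomal zone and in labeled somata).
    Per-frame integer shifts are drawn uniformly within +/-`jitter` and
    applied circularly; the true shifts are recorded for registration
    oracles.
    """
    rng = np.random.default_rng(seed)
    h, w = field_shape
    n, t_frames = fluor.clean.shape

    strio_mask = np.zeros((h, w), dtype=bool)
    strio_mask[:, : w // 3] = True

    yy, xx = np.mgrid[0:h, 0:w]
    masks: list[np.ndarray] = []
    occupied = np.zeros((h, w), dtype=bool)
    margin = roi_radius_px + 1
    for tun in fluor.tuning:
        placed = False
        for _ in range(max_placement_tries):
            cx_lo, cx_hi = (
                (margin, w // 3 - margin)
                if tun.compartment == "striosome"
                else (w // 3 + margin, w - margin)
            )
            cy = rng.integers(margin, h - margin)
            cx = rng.integers(cx_lo, cx_hi)
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= roi_radius_px**2
            if not (mask & occupied).any():
                masks.append(mask)
                occupied |= mask
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place ROIs without overlap; enlarge the field")

    from scipy.ndimage import gaussian_filter

    green_base = np.full((h, w), neuropil_level, dtype=np.float64)
    red_base = np.full((h, w), 20.0, dtype=np.float64)
    red_base[strio_mask] = 150.0
    # static speckle texture: dense neuropil labeling is spatially structured,
    # which is what makes rigid registration on the red channel well-posed
    texture = gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), sigma=1.2)
    red_base += 40.0 * texture / max(texture.std(), 1e-12)
    red_base = np.clip(red_base, 0.0, None)
    gtexture = gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), sigma=1.2)
    green_base += 10.0 * gtexture / max(gtexture.std(), 1e-12)
    green_base = np.clip(green_base, 0.0, None)
    for tun, mask in zip(fluor.tuning, masks):
        if tun.tdtomato:
            red_base[mask] = 220.0

    if jitter_amplitude_px > 0:
        shifts = rng.integers(
            -jitter_amplitude_px, jitter_amplitude_px + 1, size=(t_frames, 2)
        )
        shifts[0] = 0  # recording starts at the reference position
    else:
        shifts = np.zeros((t_frames, 2), dtype=int)

    frames = np.empty((t_frames, h, w, 2), dtype=np.float32)
    # scale traces into pixel intensities relative to their own baseline
    for t in range(t_frames):
        g = green_base.copy()
        for j, mask in enumerate(masks):
            g[mask] = fluor.clean[j, t] / 4.0
        g = g + rng.normal(0.0, pixel_noise_sigma, size=(h, w))
        r = red_base + rng.normal(0.0, pixel_noise_sigma, size=(h, w))
        dy, dx = shifts[t]
        frames[t, :, :, 0] = np.clip(np.roll(np.roll(g, dy, axis=0), dx, axis=1), 0, None)
        frames[t, :, :, 1] = np.clip(np.roll(np.roll(r, dy, axis=0), dx, axis=1), 0, None)

    return MovieStack(
        frames=frames,
        frame_rate_hz=fluor.frame_rate_hz,
        roi_masks=masks,
        striosome_neuropil_mask=strio_mask,
        true_shifts=shifts,
    )
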