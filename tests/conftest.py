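import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from striomix import synthgen

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def schedule():
    """A medium two-tone session used across tests (seeded, immutable)."""
    return synthgen.generate_task_schedule(60, seed=11)


@pytest.fixture(scope="session")
def licks(schedule):
    return synthgen.generate_licking(schedule, seed=12)


@pytest.fixture(scope="session")
def cue_neuron_session():
    """Strong cue-preferring neuron with low noise: an easy recovery target."""
    trials = synthgen.generate_task_schedule(80, seed=21)
    lick_train = synthgen.generate_licking(trials, seed=22)
    tuning = [
        synthgen.GroundTruthTuning(
            neuron_id=0,
            compartment="striosome",
            tdtomato=False,
            epoch_pref="cue",
            cue_gain_high=1.0,
            cue_gain_low=0.5,
            history_gain=0.0,
            peak_offset_s=0.8,
            noise_sigma=5.0,
        )
    ]
    fluor = synthgen.generate_fluorescence(
        trials, lick_train, tuning, spont_rate_hz=0.0, seed=23
    )
    return {"trials": trials, "licks": lick_train, "tuning": tuning, "fluor": fluor}


def make_bump_trace(
    n_frames: int,
    frame_rate_hz: float,
    event_times_s: np.ndarray,
    amplitudes: np.ndarray,
    rise_s: float = 0.2,
    decay_s: float = 1.5,
) -> np.ndarray:
    """Hand-built dF/F-like trace: kernel bumps at given times (no noise)."""
    k = synthgen.calcium_kernel(rise_s, decay_s, frame_rate_hz)
    impulses = np.zeros(n_frames)
    idx = np.round(np.asarray(event_times_s) * frame_rate_hz).astype(int)
    ok = (idx >= 0) & (idx < n_frames)
    np.add.at(impulses, idx[ok], np.asarray(amplitudes, dtype=float)[ok])
    return np.convolve(impulses, k)[:n_frames]
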