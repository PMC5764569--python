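"""Run configuration: one serializable object drives the whole pipeline.

Every stochastic stage consumes a child seed spawned deterministically from
the master seed, so a fixed config reproduces a run bit-for-bit.  Configs
round-trip through YAML/JSON unchanged (sequences are stored as lists).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "child_seeds"]

ALL_STAGES = (
    "simulate",
    "extract",
    "events",
    "metrics",
    "history",
    "behavior",
    "regress",
    "movie",
)


def _demo_epoch_mix() -> dict:
    # enriched relative to the population-wide mix so every epoch contrast
    # has usable counts at the demo scale
    return {"cue": 0.25, "lick": 0.30, "postlick": 0.08, "none": 0.37}


def _demo_epoch_amplitude_scale() -> dict:
    # cue transients are weaker than post-reward consumption transients,
    # which is also what makes the compartment cue-fraction contrast visible
    return {"cue": 0.45, "lick": 1.0, "postlick": 1.0}


def _default_profile() -> dict:
    return {"striosome": [2.0, 0.1], "matrix": [1.0, 0.4]}


@dataclass
class RunConfig:
    """Parameters for a full synthetic-experiment run."""

    seed: int = 0
    out_dir: str = "runs/demo"
    stages: list = field(default_factory=lambda: list(ALL_STAGES))

    # task schedule
    n_trials: int = 240
    p_high_cue: float = 0.5
    p_reward_high: float = 0.8
    p_reward_low: float = 0.2
    iti_range_s: list = field(default_factory=lambda: [5.25, 8.75])

    # licking
    anticipatory_rate_high: float = 6.0
    anticipatory_rate_low: float = 1.5
    history_effect: float = 0.3
    bout_rate: float = 7.0
    bout_duration_s: float = 2.5

    # neural population
    n_neurons: int = 240
    striosome_fraction: float = 0.35
    epoch_mix: dict = field(default_factory=_demo_epoch_mix)
    epoch_amplitude_scale: dict = field(default_factory=_demo_epoch_amplitude_scale)
    compartment_gain_profile: dict = field(default_factory=_default_profile)
    amplitude_median: float = 0.30
    amplitude_sigma_ln: float = 0.5
    noise_sigma: float = 65.0
    frame_rate_hz: float = 5.0

    # behavior / regression sessions
    n_behavior_sessions: int = 20
    trials_per_behavior_session: int = 60
    learning_step_session: int = 11  # 0-based index of the first learned session

    # analysis thresholds
    alpha: float = 0.01
    alpha_learning: float = 0.05
    gap_threshold_s: float = 1.0
    n_permutations: int = 200
    shuffle_repeats: int = 20
    shuffle_min_neurons: int = 10
    epoch_test: str = "signed_rank"

    # movie stage
    movie_n_neurons: int = 10
    movie_n_frames: int = 40
    movie_field: list = field(default_factory=lambda: [48, 48])
    movie_jitter_px: int = 3

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2**31 spawned from the master."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1, dtype=np.uint32)[0] % (2**31)) for s in ss.spawn(n)]
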