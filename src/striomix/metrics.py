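"""Selectivity and temporal-specificity statistics.

AUROC selectivity between trial conditions, the pairwise-correlation
reliability index, peak-time dispersion, the ridge-to-background ratio, and
the cross-neuron shuffle null that tests whether individual neurons carry
temporally specific responses (rather than the population ramp being
present in every cell).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .events import AlignedResponse, align, window_mean

__all__ = [
    "SelectivityResult",
    "auroc",
    "outcome_selectivity",
    "reliability_index",
    "peak_time_sd",
    "mean_peak_response",
    "ridge_to_background",
    "temporal_stats",
    "shuffle_across_neurons",
]


@dataclass
class SelectivityResult:
    """AUROC of one contrast with a permutation p-value."""

    unit_id: object
    auroc: float
    contrast: str
    p_value: float
    n_a: int
    n_b: int


def _auroc_stat(a: np.ndarray, b: np.ndarray) -> float:
    """AUROC via midranks: P(a > b) + 0.5 P(a = b) over all pairs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ranks = stats.rankdata(np.concatenate([a, b]))
    r_a = ranks[: a.size].sum()
    u = r_a - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def auroc(
    samples_a,
    samples_b,
    n_permutations: int = 1000,
    seed: int = 0,
    contrast: str = "a_vs_b",
    unit_id=None,
) -> SelectivityResult:
    """AUROC of condition A over condition B with a permutation test.

    The statistic is the probability that a random A-sample exceeds a random
    B-sample (ties count half); 0.5 means no selectivity.  The two-sided
    p-value comes from ``n_permutations`` seeded label shuffles of
    ``|AUROC - 0.5|``.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both sample sets must be nonempty")
    observed = _auroc_stat(a, b)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        stat = _auroc_stat(perm[: a.size], perm[a.size :])
        if abs(stat - 0.5) >= abs(observed - 0.5) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return SelectivityResult(
        unit_id=unit_id,
        auroc=observed,
        contrast=contrast,
        p_value=float(p),
        n_a=a.size,
        n_b=b.size,
    )


def outcome_selectivity(
    ztrace: np.ndarray,
    frame_rate_hz: float,
    trials: pd.DataFrame,
    lick_events: pd.DataFrame,
    quant_window_s: tuple[float, float] = (1.0, 2.0),
    unrewarded_anchor_s: float = 2.0,
    n_permutations: int = 1000,
    seed: int = 0,
    unit_id=None,
) -> dict[str, SelectivityResult]:
    """Rewarded-vs-unrewarded AUROC per cue and pooled.

    Rewarded trials are anchored to the first lick after reward delivery;
    unrewarded trials to 2 s after cue onset, a matched anchor since no
    reward (and often no lick) occurs.  The per-trial scalar is the mean
    z-scored response over ``quant_window_s`` after the anchor.  Cues
    lacking either outcome class are absent from the result.
    """
    onsets = trials["tone_onset_s"].to_numpy()
    rewarded = trials["rewarded"].to_numpy()
    first = lick_events["first_reward_lick_s"].to_numpy()

    scalars = np.full(len(trials), np.nan)
    for i in range(len(trials)):
        anchor = first[i] if rewarded[i] else onsets[i] + unrewarded_anchor_s
        if not np.isfinite(anchor):
            continue
        scalars[i] = window_mean(
            ztrace, frame_rate_hz, anchor + quant_window_s[0], anchor + quant_window_s[1]
        )

    out: dict[str, SelectivityResult] = {}
    cue_arr = trials["cue"].to_numpy()
    for label, mask in (
        ("high", cue_arr == "high"),
        ("low", cue_arr == "low"),
        ("pooled", np.ones(len(trials), dtype=bool)),
    ):
        rew = scalars[mask & rewarded & np.isfinite(scalars)]
        unr = scalars[mask & ~rewarded & np.isfinite(scalars)]
        if rew.size == 0 or unr.size == 0:
            continue
        out[label] = auroc(
            rew,
            unr,
            n_permutations=n_permutations,
            seed=seed,
            contrast=f"rewarded_vs_unrewarded_{label}",
            unit_id=unit_id,
        )
    return out


# ---------------------------------------------------------------------------
# temporal statistics
# ---------------------------------------------------------------------------

def reliability_index(aligned: np.ndarray) -> float:
    """Mean Pearson correlation over all pairwise trial combinations.

    Constant rows cannot be correlated; their pairs are skipped with a
    warning.  Requires at least two usable trials.
    """
    mat = np.asarray(aligned, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need a (n_trials >= 2, n_time) response matrix")
    const = mat.std(axis=1) == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant trial rows skipped in reliability index",
            stacklevel=2,
        )
    keep = np.where(~const)[0]
    if keep.size < 2:
        return np.nan
    sub = mat[keep]
    corr = np.corrcoef(sub)
    iu = np.triu_indices(len(keep), k=1)
    return float(corr[iu].mean())


def peak_time_sd(aligned: np.ndarray, time_axis_s: np.ndarray) -> float:
    """SD across trials of the per-trial peak time (s)."""
    mat = np.asarray(aligned, dtype=float)
    peaks = time_axis_s[np.argmax(mat, axis=1)]
    return float(np.std(peaks, ddof=1)) if len(peaks) > 1 else np.nan


def mean_peak_response(aligned: np.ndarray) -> float:
    """Peak of the trial-averaged response."""
    return float(np.asarray(aligned, dtype=float).mean(axis=0).max())


def ridge_to_background(
    session_averaged: np.ndarray, ridge_halfwidth: int = 2
) -> float:
    """Mean of the 5 samples (1 s at 5 Hz) around the peak over the rest.

    The ridge window is truncated at the trace boundaries.  A non-positive
    background mean yields +inf with a warning.
    """
    resp = np.asarray(session_averaged, dtype=float)
    if resp.size <= 2 * ridge_halfwidth + 1:
        raise ValueError("response too short for a ridge window")
    peak = int(np.argmax(resp))
    lo = max(peak - ridge_halfwidth, 0)
    hi = min(peak + ridge_halfwidth + 1, resp.size)
    ridge = resp[lo:hi].mean()
    mask = np.ones(resp.size, dtype=bool)
    mask[lo:hi] = False
    background = resp[mask].mean()
    if background <= 0:
        warnings.warn("non-positive background; ridge ratio is infinite", stacklevel=2)
        return float("inf")
    return float(ridge / background)


def temporal_stats(aligned: np.ndarray, time_axis_s: np.ndarray) -> dict[str, float]:
    """Reliability, peak-time SD, mean peak response, ridge ratio for one neuron."""
    return {
        "reliability": reliability_index(aligned),
        "peak_time_sd_s": peak_time_sd(aligned, time_axis_s),
        "mean_peak_response": mean_peak_response(aligned),
        "ridge_ratio": ridge_to_background(np.asarray(aligned).mean(axis=0)),
    }


# ---------------------------------------------------------------------------
# cross-neuron shuffle null
# ---------------------------------------------------------------------------

def _derangement(n: int, rng: np.random.Generator, max_tries: int = 1000) -> np.ndarray:
    """Random permutation of range(n) without fixed points (n >= 2)."""
    for _ in range(max_tries):
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm
    raise RuntimeError("failed to draw a derangement")


def shuffle_across_neurons(
    responses: dict,
    time_axis_s: np.ndarray,
    n_repeats: int = 20,
    min_neurons: int = 10,
    seed: int = 0,
) -> dict:
    """Cross-neuron shuffle null for temporal specificity.

    ``responses`` maps neuron id -> (n_trials, n_time) aligned matrix; all
    matrices must share the trial set.  Each shuffle repeat replaces every
    neuron's response in each trial with the same trial's response from
    another simultaneously recorded task-modulated neuron, by drawing a
    random neuron permutation (excluding self-assignment) per trial.  The
    per-neuron metrics of each repeat are averaged over the 20 repeats, and
    observed vs shuffled distributions are compared by rank-sum tests.
    Because each trial's rows are only permuted across neurons, the
    population trial-mean field is exactly preserved.
    """
    ids = list(responses)
    if len(ids) < min_neurons:
        raise ValueError(
            f"need at least {min_neurons} simultaneously recorded task-modulated "
            f"neurons, got {len(ids)}"
        )
    mats = np.stack([np.asarray(responses[i], dtype=float) for i in ids])
    n_neurons, n_trials, _ = mats.shape

    def stats_frame(stack: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"neuron_id": ids[j], **temporal_stats(stack[j], time_axis_s)}
                for j in range(n_neurons)
            ]
        )

    observed = stats_frame(mats)
    rng = np.random.default_rng(seed)
    per_repeat = []
    shuffled_field = None
    for _ in range(n_repeats):
        shuffled = np.empty_like(mats)
        for t in range(n_trials):
            perm = _derangement(n_neurons, rng)
            shuffled[:, t, :] = mats[perm, t, :]
        per_repeat.append(stats_frame(shuffled).set_index("neuron_id"))
        shuffled_field = shuffled.mean(axis=0)
    shuffled_mean = (
        sum(per_repeat) / n_repeats
    ).reset_index()  # mean of the repeat outcomes per neuron

    tests = {}
    for col in ("reliability", "peak_time_sd_s", "mean_peak_response", "ridge_ratio"):
        obs = observed[col].to_numpy()
        shf = shuffled_mean[col].to_numpy()
        ok = np.isfinite(obs) & np.isfinite(shf)
        if ok.sum() >= 2:
            tests[col] = float(
                stats.mannwhitneyu(obs[ok], shf[ok], alternative="two-sided").pvalue
            )
        else:
            tests[col] = np.nan
    return {
        "observed": observed,
        "shuffled": shuffled_mean,
        "ranksum_p": tests,
        "population_mean_field_observed": mats.mean(axis=0),
        "population_mean_field_shuffled": shuffled_field,
        "n_repeats": n_repeats,
    }
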