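"""Licking quantification, learning criterion, and training phases.

Learning in the two-tone task is read out behaviorally: with training the
anticipatory lick rate during the tone and the 0.5 s reward delay becomes
higher for the high-probability cue.  A mouse counts as trained from the
first session at which at least 2 of the last 3 consecutive sessions show a
significant high-vs-low difference (two-sided t-test, alpha = 0.05).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .synthgen import REWARD_DELAY_S

__all__ = [
    "lick_psth",
    "anticipatory_measure",
    "session_cue_test",
    "learning_criterion",
]


def lick_psth(
    licks: np.ndarray,
    event_times_s: np.ndarray,
    bin_s: float = 0.2,
    window_s: tuple[float, float] = (-2.0, 6.0),
) -> dict:
    """Event-locked lick rate histogram.

    Returns per-trial binned rates (Hz), bin centers, and the trial-mean
    rate with its SEM.
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be > 0")
    lo, hi = window_s
    if hi <= lo:
        raise ValueError("empty PSTH window")
    licks = np.asarray(licks, dtype=float)
    edges = np.arange(lo, hi + bin_s / 2, bin_s)
    rates = np.empty((len(event_times_s), len(edges) - 1))
    for i, t in enumerate(np.asarray(event_times_s, dtype=float)):
        counts, _ = np.histogram(licks - t, bins=edges)
        rates[i] = counts / bin_s
    mean = rates.mean(axis=0) if len(rates) else np.zeros(len(edges) - 1)
    sem = (
        rates.std(axis=0, ddof=1) / np.sqrt(len(rates))
        if len(rates) > 1
        else np.zeros(len(edges) - 1)
    )
    centers = edges[:-1] + bin_s / 2
    return {"rates": rates, "bin_centers_s": centers, "mean": mean, "sem": sem}


def anticipatory_measure(
    licks: np.ndarray,
    trials: pd.DataFrame,
    include_delay: bool = True,
    baseline_window_s: float = 2.0,
) -> pd.DataFrame:
    """Per-trial anticipatory lick counts with session z-scores.

    Anticipatory licks fall in [tone onset, tone offset (+ 0.5 s delay when
    ``include_delay``)].  The z-score compares each trial's anticipatory
    rate with the distribution of baseline rates over the 2 s preceding the
    tone, pooled across the session's trials.
    """
    if len(trials) == 0:
        raise ValueError("trials must be nonempty")
    licks = np.asarray(licks, dtype=float)
    onsets = trials["tone_onset_s"].to_numpy()
    ends = trials["tone_offset_s"].to_numpy() + (REWARD_DELAY_S if include_delay else 0.0)
    counts = np.array(
        [np.sum((licks >= a) & (licks < b)) for a, b in zip(onsets, ends)], dtype=float
    )
    rates = counts / (ends - onsets)
    base_counts = np.array(
        [np.sum((licks >= t - baseline_window_s) & (licks < t)) for t in onsets],
        dtype=float,
    )
    base_rates = base_counts / baseline_window_s
    mu, sd = base_rates.mean(), base_rates.std(ddof=0)
    if sd > 0:
        z = (rates - mu) / sd
    else:
        z = np.zeros_like(rates)
        z[rates > mu] = np.inf
        z[rates < mu] = -np.inf
    return pd.DataFrame(
        {
            "trial_id": trials["trial_id"].to_numpy(),
            "cue": trials["cue"].to_numpy(),
            "anticipatory_count": counts,
            "anticipatory_rate_hz": rates,
            "z": z,
        }
    )


def session_cue_test(
    counts_high: np.ndarray, counts_low: np.ndarray
) -> float:
    """Two-sided Welch t-test p on anticipatory counts, high vs low cue.

    Returns NaN when either cue has fewer than two trials (test undefined).
    """
    a = np.asarray(counts_high, dtype=float)
    b = np.asarray(counts_low, dtype=float)
    if a.size < 2 or b.size < 2:
        return np.nan
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def learning_criterion(
    session_counts: list[tuple[np.ndarray, np.ndarray]],
    alpha: float = 0.05,
    n_overtraining: int = 0,
) -> pd.DataFrame:
    """Phase labels from the 2-of-3-sessions learning rule.

    ``session_counts`` is a chronological list of (high-cue counts, low-cue
    counts) per session.  Each session gets a two-sided Welch t-test; the
    trained flag is raised at the first session s for which at least 2 of
    the (up to) 3 consecutive sessions ending at s are significant.
    Sessions before that are acquisition; the flagging session and later
    are criterion, except the final ``n_overtraining`` sessions, which are
    assigned the overtraining phase by protocol.
    """
    if len(session_counts) < 3:
        raise ValueError("need at least 3 sessions")
    p_values = np.array([session_cue_test(h, l) for h, l in session_counts])
    significant = np.isfinite(p_values) & (p_values < alpha)

    criterion_session: int | None = None
    for s in range(1, len(significant)):
        window = significant[max(0, s - 2) : s + 1]
        if window.sum() >= 2:
            criterion_session = s
            break

    n = len(session_counts)
    phases = []
    for s in range(n):
        if criterion_session is None or s < criterion_session:
            phase = "acquisition"
        elif n_overtraining and s >= n - n_overtraining:
            phase = "overtraining"
        else:
            phase = "criterion"
        phases.append(phase)
    return pd.DataFrame(
        {
            "session_index": np.arange(n),
            "p_value": p_values,
            "significant": significant,
            "phase": phases,
            "criterion_met": [
                criterion_session is not None and s >= criterion_session
                for s in range(n)
            ],
        }
    )
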