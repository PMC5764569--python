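"""Reward-history labeling and the history modulation index (HMI).

For currently rewarded trials, the post-reward licking response (mean
z-scored dF/F over a 2 s window starting 1 s after reward delivery) is
min-max normalized across the neuron's included trials and split by the
outcome of the trial one (or two) back:

    HMI = (mean | previous rewarded - mean | previous unrewarded)
          / (mean | previous rewarded + mean | previous unrewarded)

HMI lies in [-1, 1]; a response that is larger after unrewarded-previous
trials gives a negative HMI.  Matrix neurons carry a stronger (more
negative) HMI than striosomal neurons under the generator's default gains.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .events import window_mean

__all__ = [
    "label_history",
    "normalized_window_response",
    "history_modulation_index",
    "population_hmi",
    "compare_history_effects",
    "cue_period_history",
    "licking_history_control",
]


def label_history(trials: pd.DataFrame, lag: int = 1) -> pd.Series:
    """Label every trial with the rewarded status of the trial ``lag`` back.

    The first ``lag`` trials carry NaN (no history).  The current trial's
    cue identity and outcome play no role in the label.
    """
    if lag not in (1, 2):
        raise ValueError(f"lag must be 1 or 2, got {lag}")
    rewarded = trials["rewarded"].astype(float)
    return rewarded.shift(lag).rename(f"prev_rewarded_lag{lag}")


def normalized_window_response(
    ztrace: np.ndarray,
    frame_rate_hz: float,
    trials: pd.DataFrame,
    window_s: tuple[float, float] = (1.0, 3.0),
) -> pd.Series | None:
    """Per-trial post-reward responses of currently rewarded trials in [0, 1].

    The per-trial scalar is the mean z over ``window_s`` relative to reward
    delivery, min-max scaled across this neuron's included trials.  Returns
    None (with a warning) when the response range is zero or fewer than two
    rewarded trials exist.
    """
    rewarded = trials["rewarded"].to_numpy()
    reward_times = trials["reward_time_s"].to_numpy()
    vals, idx = [], []
    for i in range(len(trials)):
        if not rewarded[i] or not np.isfinite(reward_times[i]):
            continue
        v = window_mean(
            ztrace,
            frame_rate_hz,
            reward_times[i] + window_s[0],
            reward_times[i] + window_s[1],
        )
        if np.isfinite(v):
            vals.append(v)
            idx.append(trials["trial_id"].iat[i])
    if len(vals) < 2:
        warnings.warn("fewer than two rewarded trials; neuron excluded", stacklevel=2)
        return None
    arr = np.asarray(vals)
    rng_ = arr.max() - arr.min()
    if rng_ == 0:
        warnings.warn("zero response range; neuron excluded from HMI", stacklevel=2)
        return None
    return pd.Series((arr - arr.min()) / rng_, index=pd.Index(idx, name="trial_id"))


def history_modulation_index(
    norm_responses: pd.Series, labels: pd.Series
) -> dict | None:
    """HMI from normalized responses and previous-outcome labels.

    ``labels`` is indexed by trial_id (1.0 = previously rewarded, 0.0 =
    previously unrewarded, NaN = no history).  Returns None when either
    label class is empty or the denominator vanishes.
    """
    lab = labels.reindex(norm_responses.index)
    r = norm_responses[lab == 1.0]
    u = norm_responses[lab == 0.0]
    if len(r) == 0 or len(u) == 0:
        return None
    mean_r, mean_u = float(r.mean()), float(u.mean())
    denom = mean_r + mean_u
    if denom == 0:
        warnings.warn("zero HMI denominator; neuron excluded", stacklevel=2)
        return None
    return {
        "mean_norm_response_prev_rewarded": mean_r,
        "mean_norm_response_prev_unrewarded": mean_u,
        "hmi": (mean_r - mean_u) / denom,
        "n_prev_rewarded": int(len(r)),
        "n_prev_unrewarded": int(len(u)),
    }


def population_hmi(
    ztraces: np.ndarray,
    frame_rate_hz: float,
    trials: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    lags: tuple[int, ...] = (1, 2),
    window_s: tuple[float, float] = (1.0, 3.0),
) -> pd.DataFrame:
    """HMI per neuron and lag for a (n_neurons, T) z-scored dF/F array."""
    labels = {lag: label_history(trials, lag) for lag in lags}
    for lag in lags:
        labels[lag].index = trials["trial_id"].to_numpy()
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(ztraces.shape[0]):
            norm = normalized_window_response(
                ztraces[j], frame_rate_hz, trials, window_s
            )
            if norm is None:
                continue
            for lag in lags:
                res = history_modulation_index(norm, labels[lag])
                if res is None:
                    continue
                rows.append({"neuron_id": j, "lag": lag, **res})
    out = pd.DataFrame(rows)
    if meta is not None and len(out):
        out = out.merge(meta[["neuron_id", "compartment"]], on="neuron_id", how="left")
    return out


def cue_period_history(
    ztraces: np.ndarray,
    frame_rate_hz: float,
    trials: pd.DataFrame,
    window_s: tuple[float, float] = (0.0, 2.0),
) -> dict:
    """History split of cue-period z-scores (no min-max normalization).

    Mean z over the 2 s post-tone window, split by previous-trial outcome,
    pooled over neurons, with a signed-rank test on the per-neuron means.
    """
    lab = label_history(trials, 1).to_numpy()
    onsets = trials["tone_onset_s"].to_numpy()
    per_neuron_r, per_neuron_u = [], []
    for j in range(ztraces.shape[0]):
        resp = np.array(
            [
                window_mean(
                    ztraces[j], frame_rate_hz, t + window_s[0], t + window_s[1]
                )
                for t in onsets
            ]
        )
        r = resp[lab == 1.0]
        u = resp[lab == 0.0]
        if r.size and u.size:
            per_neuron_r.append(np.nanmean(r))
            per_neuron_u.append(np.nanmean(u))
    r = np.asarray(per_neuron_r)
    u = np.asarray(per_neuron_u)
    if r.size < 2:
        return {"mean_prev_rewarded": np.nan, "mean_prev_unrewarded": np.nan, "p": np.nan}
    diff = r - u
    p = 1.0 if np.allclose(diff, 0) else float(
        stats.wilcoxon(diff, alternative="two-sided").pvalue
    )
    return {
        "mean_prev_rewarded": float(r.mean()),
        "mean_prev_unrewarded": float(u.mean()),
        "p": p,
    }


def licking_history_control(
    sessions: list[dict],
    anticipatory_window_s: tuple[float, float] = (0.0, 2.0),
    post_reward_window_s: tuple[float, float] = (0.0, 2.5),
) -> dict:
    """Signed-rank tests of licking measures by previous-trial outcome.

    Each session dict supplies ``trials`` and ``licks``.  Per session we
    average the anticipatory lick count (tone onset + window, all trials)
    and the post-reward lick count (currently rewarded trials) separately
    for previously rewarded and previously unrewarded trials; the paired
    session-level means are compared by Wilcoxon signed-rank.  In the
    generator, only anticipatory licking carries a history effect.
    """
    ant_r, ant_u, post_r, post_u = [], [], [], []
    for sess in sessions:
        trials, licks = sess["trials"], np.asarray(sess["licks"])
        lab = label_history(trials, 1).to_numpy()
        onsets = trials["tone_onset_s"].to_numpy()
        reward_times = trials["reward_time_s"].to_numpy()
        rewarded = trials["rewarded"].to_numpy()
        ant = np.array(
            [
                np.sum(
                    (licks >= t + anticipatory_window_s[0])
                    & (licks < t + anticipatory_window_s[1])
                )
                for t in onsets
            ],
            dtype=float,
        )
        post = np.full(len(trials), np.nan)
        for i in range(len(trials)):
            if rewarded[i] and np.isfinite(reward_times[i]):
                post[i] = np.sum(
                    (licks >= reward_times[i] + post_reward_window_s[0])
                    & (licks < reward_times[i] + post_reward_window_s[1])
                )
        for vals, acc_r, acc_u, extra in (
            (ant, ant_r, ant_u, np.ones(len(trials), dtype=bool)),
            (post, post_r, post_u, rewarded),
        ):
            mr = (lab == 1.0) & extra & np.isfinite(vals)
            mu = (lab == 0.0) & extra & np.isfinite(vals)
            if mr.any() and mu.any():
                acc_r.append(vals[mr].mean())
                acc_u.append(vals[mu].mean())

    def _signed_rank(x, y):
        x, y = np.asarray(x), np.asarray(y)
        if x.size < 2 or np.allclose(x - y, 0):
            return np.nan
        return float(stats.wilcoxon(x - y, alternative="two-sided").pvalue)

    return {
        "anticipatory": {
            "mean_prev_rewarded": float(np.mean(ant_r)) if ant_r else np.nan,
            "mean_prev_unrewarded": float(np.mean(ant_u)) if ant_u else np.nan,
            "p": _signed_rank(ant_r, ant_u),
        },
        "post_reward": {
            "mean_prev_rewarded": float(np.mean(post_r)) if post_r else np.nan,
            "mean_prev_unrewarded": float(np.mean(post_u)) if post_u else np.nan,
            "p": _signed_rank(post_r, post_u),
        },
    }


def compare_history_effects(hmi_df: pd.DataFrame, group_col: str = "compartment") -> dict:
    """Compartment and lag comparisons of the HMI distribution.

    Rank-sum between compartments on lag-1 HMI; signed-rank on |HMI| at
    lag 1 vs lag 2 within neurons that have both.  Degenerate groups are
    reported as untestable (NaN p).
    """
    out: dict = {}
    lag1 = hmi_df[hmi_df["lag"] == 1]
    if group_col in hmi_df.columns:
        grp = {name: df["hmi"].to_numpy() for name, df in lag1.groupby(group_col)}
        out["group_means"] = {k: float(v.mean()) for k, v in grp.items() if v.size}
        if (
            "striosome" in grp
            and "matrix" in grp
            and grp["striosome"].size >= 2
            and grp["matrix"].size >= 2
        ):
            out["p_compartment_ranksum"] = float(
                stats.mannwhitneyu(
                    grp["striosome"], grp["matrix"], alternative="two-sided"
                ).pvalue
            )
        else:
            out["p_compartment_ranksum"] = np.nan

    wide = hmi_df.pivot_table(index="neuron_id", columns="lag", values="hmi")
    if {1, 2} <= set(wide.columns):
        both = wide.dropna(subset=[1, 2])
        if len(both) >= 2:
            d = both[1].abs() - both[2].abs()
            out["mean_abs_hmi_lag1"] = float(both[1].abs().mean())
            out["mean_abs_hmi_lag2"] = float(both[2].abs().mean())
            out["p_lag_signed_rank"] = (
                1.0
                if np.allclose(d, 0)
                else float(stats.wilcoxon(d, alternative="two-sided").pvalue)
            )
        else:
            out["p_lag_signed_rank"] = np.nan
    return out
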