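"""Session-level regression of neuropil activation on licking performance.

For every session the tone-evoked licking and tone-evoked aggregate dF/F
are expressed as z-scores against the 1 s pre-cue baseline of the same
session and averaged per cue.  Simple OLS models (dF/F z on lick z) are fit
per compartment for the high cue, the low cue, and the high-minus-low
difference, plus one combined model pooling compartments whose residuals
are compared between compartments by a paired t-test — a session-matched
way to ask whether striosomal activation exceeds what licking predicts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .events import pooled_baseline, window_mean, zscore_trace

__all__ = ["build_session_table", "fit_models"]

CONDITIONS = ("high", "low", "difference")


def _session_z_means(
    trace: np.ndarray,
    frame_rate_hz: float,
    trials: pd.DataFrame,
    tone_window_s: tuple[float, float],
    baseline_s: float,
) -> dict[str, float]:
    """Per-cue session means of per-trial z-scored tone-evoked responses."""
    onsets = trials["tone_onset_s"].to_numpy()
    mean_b, sd_b = pooled_baseline(
        trace, frame_rate_hz, onsets, window_s=(-baseline_s, 0.0)
    )
    z = zscore_trace(trace, mean_b, sd_b)
    resp = np.array(
        [
            window_mean(z, frame_rate_hz, t + tone_window_s[0], t + tone_window_s[1])
            for t in onsets
        ]
    )
    out = {}
    for cue in ("high", "low"):
        mask = (trials["cue"] == cue).to_numpy() & np.isfinite(resp)
        out[cue] = float(resp[mask].mean()) if mask.any() else np.nan
    out["difference"] = out["high"] - out["low"]
    return out


def _lick_rate_trace(
    licks: np.ndarray, n_frames: int, frame_rate_hz: float
) -> np.ndarray:
    """Binned lick rate (Hz) on the imaging frame grid."""
    edges = np.arange(n_frames + 1) / frame_rate_hz
    counts, _ = np.histogram(np.asarray(licks, dtype=float), bins=edges)
    return counts * frame_rate_hz


def build_session_table(
    sessions: list[dict],
    tone_window_s: tuple[float, float] = (0.0, 2.0),
    baseline_s: float = 1.0,
) -> pd.DataFrame:
    """One row per session x compartment x condition with lick_z and dff_z.

    Each session dict supplies ``session_id``, ``trials``, ``licks``,
    ``frame_rate_hz``, and aggregate fluorescence traces under
    ``striosome`` and ``matrix``.  Sessions missing a compartment are
    dropped with a warning.  The licking measure is shared by both
    compartments of a session (one behavior, two simultaneously imaged
    regions).
    """
    rows = []
    for sess in sessions:
        if not {"striosome", "matrix"} <= set(sess):
            warnings.warn(
                f"session {sess.get('session_id')!r} missing a compartment; dropped",
                stacklevel=2,
            )
            continue
        trials = sess["trials"]
        rate = sess["frame_rate_hz"]
        n_frames = len(np.asarray(sess["striosome"]))
        lick_trace = _lick_rate_trace(sess["licks"], n_frames, rate)
        lick_z = _session_z_means(lick_trace, rate, trials, tone_window_s, baseline_s)
        for comp in ("striosome", "matrix"):
            dff_z = _session_z_means(
                np.asarray(sess[comp], dtype=float), rate, trials, tone_window_s, baseline_s
            )
            for cond in CONDITIONS:
                rows.append(
                    {
                        "session_id": sess["session_id"],
                        "compartment": comp,
                        "cue_condition": cond,
                        "lick_z": lick_z[cond],
                        "dff_z": dff_z[cond],
                    }
                )
    return pd.DataFrame(rows)


def _ols(x: np.ndarray, y: np.ndarray) -> dict:
    X = sm.add_constant(np.asarray(x, dtype=float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant regressor)")
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return {
        "coefficient": float(fit.params[1]),
        "coefficient_p": float(fit.pvalues[1]),
        "intercept": float(fit.params[0]),
        "r_squared": float(fit.rsquared),
        "residuals": np.asarray(fit.resid),
    }


def fit_models(table: pd.DataFrame, min_sessions: int = 3) -> dict:
    """Per-compartment and combined regressions with residual comparison.

    For each cue condition: separate striosome and matrix OLS fits of
    ``dff_z`` on ``lick_z``; a combined fit pooling both compartments; the
    combined model's mean residual per compartment with a paired t-test
    across sessions.  With equal session counts the two compartments' mean
    residuals are exact negatives (OLS residuals sum to zero).
    """
    results: dict = {}
    for cond in CONDITIONS:
        sub = table[table["cue_condition"] == cond]
        cond_res: dict = {}
        for comp in ("striosome", "matrix"):
            g = sub[sub["compartment"] == comp].dropna(subset=["lick_z", "dff_z"])
            if len(g) < min_sessions:
                raise ValueError(f"need >= {min_sessions} sessions for {comp}/{cond}")
            fit = _ols(g["lick_z"], g["dff_z"])
            cond_res[comp] = {k: v for k, v in fit.items() if k != "residuals"}

        pooled = sub.dropna(subset=["lick_z", "dff_z"]).reset_index(drop=True)
        fit = _ols(pooled["lick_z"], pooled["dff_z"])
        pooled = pooled.assign(residual=fit["residuals"])
        res_wide = pooled.pivot_table(
            index="session_id", columns="compartment", values="residual"
        ).dropna()
        t, p = stats.ttest_rel(res_wide["striosome"], res_wide["matrix"])
        cond_res["combined"] = {
            "coefficient": fit["coefficient"],
            "coefficient_p": fit["coefficient_p"],
            "intercept": fit["intercept"],
            "r_squared": fit["r_squared"],
            "residual_mean_striosome": float(res_wide["striosome"].mean()),
            "residual_sem_striosome": float(
                res_wide["striosome"].std(ddof=1) / np.sqrt(len(res_wide))
            ),
            "residual_mean_matrix": float(res_wide["matrix"].mean()),
            "residual_sem_matrix": float(
                res_wide["matrix"].std(ddof=1) / np.sqrt(len(res_wide))
            ),
            "residual_paired_t": float(t),
            "residual_paired_p": float(p),
        }
        results[cond] = cond_res
    return results
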