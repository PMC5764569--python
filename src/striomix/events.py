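"""Event-aligned tensors, z-scoring, lick bouts, and epoch classification.

The conditioning task has three response epochs per trial: the cue
(tone + reward delay), the post-reward licking period, and the period just
after licking ends.  A neuron is *task-modulated* if its activity shows a
significant increase from the pre-event baseline in any of the
corresponding alignments (tone onset, first lick after reward, last lick of
the consummatory bout), and *selective* for an epoch when only that epoch's
test is significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AlignedResponse",
    "EpochClassification",
    "detect_bout_end",
    "trial_lick_events",
    "align",
    "pooled_baseline",
    "zscore_aligned",
    "zscore_trace",
    "window_mean",
    "classify_epochs",
    "classify_population",
    "epoch_fractions",
    "fisher_exact_counts",
    "peak_sort",
    "aggregate_region_response",
]

FRAME_RATE_HZ = 5.0
EPOCH_NAMES = ("cue", "lick", "postlick")


# ---------------------------------------------------------------------------
# lick bouts
# ---------------------------------------------------------------------------

def detect_bout_end(
    licks: np.ndarray,
    reward_time_s: float,
    next_tone_onset_s: float,
    gap_threshold_s: float = 1.0,
) -> tuple[float, float] | None:
    """Delimit the consummatory lick bout of one rewarded trial.

    The bout starts at the first lick at or after reward delivery and runs
    through the maximal chain of licks whose successive gaps are below
    ``gap_threshold_s``.  Returns ``(first_reward_lick_s, last_lick_s)``, or
    ``None`` when the trial is excluded: no lick after reward, or the bout
    extends past the next tone onset (the animal never stopped licking, so
    no end time can be assigned).
    """
    licks = np.asarray(licks)
    after = licks[licks >= reward_time_s]
    if after.size == 0:
        return None
    first = after[0]
    last = first
    for t in after[1:]:
        if t - last < gap_threshold_s:
            last = t
        else:
            break
    if last >= next_tone_onset_s:
        return None
    return float(first), float(last)


def trial_lick_events(
    trials: pd.DataFrame,
    licks: np.ndarray,
    gap_threshold_s: float = 1.0,
    final_horizon_s: float = 8.75,
) -> pd.DataFrame:
    """Per-trial lick landmarks: first reward lick, last lick, inclusion flag.

    Rows align with ``trials``; unrewarded trials and excluded trials carry
    NaN landmarks.  The last trial's bout is bounded by a nominal horizon in
    place of the (nonexistent) next tone onset.
    """
    n = len(trials)
    first = np.full(n, np.nan)
    last = np.full(n, np.nan)
    included = np.zeros(n, dtype=bool)
    onsets = trials["tone_onset_s"].to_numpy()
    for i in range(n):
        if not trials["rewarded"].iat[i]:
            continue
        nxt = onsets[i + 1] if i + 1 < n else float(
            trials["reward_time_s"].iat[i] + final_horizon_s
        )
        bout = detect_bout_end(
            licks, trials["reward_time_s"].iat[i], nxt, gap_threshold_s
        )
        if bout is not None:
            first[i], last[i] = bout
            included[i] = True
    return pd.DataFrame(
        {
            "trial_id": trials["trial_id"].to_numpy(),
            "first_reward_lick_s": first,
            "last_lick_s": last,
            "included": included,
        }
    )


# ---------------------------------------------------------------------------
# alignment and z-scoring
# ---------------------------------------------------------------------------

@dataclass
class AlignedResponse:
    """Trial x time tensor locked to a named event (uniform 5 Hz time axis)."""

    values: np.ndarray  # (n_trials, n_time)
    time_axis_s: np.ndarray
    alignment: str
    included_trials: np.ndarray  # trial ids, one per row

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def trial_mean(self) -> np.ndarray:
        return self.values.mean(axis=0)


def align(
    trace: np.ndarray,
    frame_rate_hz: float,
    event_times_s: np.ndarray,
    window_s: tuple[float, float] = (-1.0, 3.0),
    trial_ids: np.ndarray | None = None,
    alignment: str = "event",
    out_rate_hz: float = FRAME_RATE_HZ,
) -> AlignedResponse:
    """Cut a trace into event-locked rows on a uniform relative time grid.

    The relative grid runs from ``window_s[0]`` to ``window_s[1]`` inclusive
    at ``1/out_rate_hz`` steps; rows are linear interpolations of the trace.
    Events with NaN times or windows extending beyond the session are
    dropped and omitted from ``included_trials``.
    """
    trace = np.asarray(trace, dtype=float)
    event_times_s = np.asarray(event_times_s, dtype=float)
    if trial_ids is None:
        trial_ids = np.arange(len(event_times_s))
    t_session = np.arange(trace.size) / frame_rate_hz
    n_steps = int(round((window_s[1] - window_s[0]) * out_rate_hz))
    rel = window_s[0] + np.arange(n_steps + 1) / out_rate_hz

    rows, kept = [], []
    t_max = t_session[-1] if trace.size else 0.0
    for tid, ev in zip(trial_ids, event_times_s):
        if not np.isfinite(ev):
            continue
        if ev + rel[0] < 0.0 or ev + rel[-1] > t_max:
            continue
        rows.append(np.interp(ev + rel, t_session, trace))
        kept.append(tid)
    if not rows:
        warnings.warn("no events could be aligned within the session", stacklevel=2)
        values = np.empty((0, rel.size))
    else:
        values = np.vstack(rows)
    return AlignedResponse(
        values=values,
        time_axis_s=rel,
        alignment=alignment,
        included_trials=np.asarray(kept, dtype=int),
    )


def pooled_baseline(
    trace: np.ndarray,
    frame_rate_hz: float,
    reference_times_s: np.ndarray,
    window_s: tuple[float, float] = (-1.0, 0.0),
) -> tuple[float, float]:
    """Session-pooled baseline mean/SD from windows before reference events.

    With tone onsets as references and the default window this is the 1 s
    pre-tone baseline; the last second of each inter-trial interval is the
    same set of samples.
    """
    samples = []
    for t in np.asarray(reference_times_s, dtype=float):
        if not np.isfinite(t):
            continue
        seg = window_samples(trace, frame_rate_hz, t + window_s[0], t + window_s[1])
        if seg.size:
            samples.append(seg)
    if not samples:
        raise ValueError("no baseline samples available")
    pooled = np.concatenate(samples)
    return float(pooled.mean()), float(pooled.std(ddof=0))


def zscore_trace(trace: np.ndarray, mean: float, sd: float) -> np.ndarray:
    if sd <= 0:
        raise ValueError("baseline SD must be > 0 for z-scoring")
    return (np.asarray(trace, dtype=float) - mean) / sd


def zscore_aligned(aligned: AlignedResponse, mean: float, sd: float) -> AlignedResponse:
    """Z-score an aligned tensor against precomputed baseline statistics."""
    return AlignedResponse(
        values=zscore_trace(aligned.values, mean, sd),
        time_axis_s=aligned.time_axis_s,
        alignment=aligned.alignment,
        included_trials=aligned.included_trials,
    )


def window_samples(
    trace: np.ndarray, frame_rate_hz: float, t0: float, t1: float
) -> np.ndarray:
    """Samples of a session trace with timestamps in [t0, t1)."""
    i0 = int(np.ceil(t0 * frame_rate_hz - 1e-9))
    i1 = int(np.ceil(t1 * frame_rate_hz - 1e-9))
    i0 = max(i0, 0)
    i1 = min(i1, len(trace))
    return np.asarray(trace[i0:i1], dtype=float)


def window_mean(trace: np.ndarray, frame_rate_hz: float, t0: float, t1: float) -> float:
    seg = window_samples(trace, frame_rate_hz, t0, t1)
    return float(seg.mean()) if seg.size else np.nan


# ---------------------------------------------------------------------------
# epoch classification
# ---------------------------------------------------------------------------

@dataclass
class EpochClassification:
    """Per-neuron task-modulation flags for the three task epochs."""

    neuron_id: int
    cue_mod: bool
    lick_mod: bool
    postlick_mod: bool
    p_values: dict = field(default_factory=dict)
    indeterminate: bool = False

    @property
    def task_mod(self) -> bool:
        return self.cue_mod or self.lick_mod or self.postlick_mod

    @property
    def selective_epoch(self) -> str:
        flags = [self.cue_mod, self.lick_mod, self.postlick_mod]
        k = sum(flags)
        if k == 0:
            return "none"
        if k > 1:
            return "multiple"
        return EPOCH_NAMES[flags.index(True)]


def _paired_increase_p(
    response: np.ndarray, baseline: np.ndarray, test: str
) -> float:
    """One-sided p for response > baseline on paired per-trial means."""
    response = np.asarray(response, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    ok = np.isfinite(response) & np.isfinite(baseline)
    response, baseline = response[ok], baseline[ok]
    if response.size < 2:
        return 1.0
    if test == "signed_rank":
        diff = response - baseline
        if np.allclose(diff, 0.0):
            return 1.0
        return float(stats.wilcoxon(diff, alternative="greater").pvalue)
    if test == "rank_sum":
        return float(
            stats.mannwhitneyu(response, baseline, alternative="greater").pvalue
        )
    raise ValueError(f"unknown test {test!r}")


def classify_epochs(
    trace: np.ndarray,
    frame_rate_hz: float,
    trials: pd.DataFrame,
    lick_events: pd.DataFrame | None = None,
    licks: np.ndarray | None = None,
    alpha: float = 0.01,
    min_trials: int = 10,
    cue_window_s: float = 2.0,
    postlick_window_s: float = 1.0,
    baseline_s: float = 1.0,
    test: str = "signed_rank",
    gap_threshold_s: float = 1.0,
    neuron_id: int = 0,
) -> EpochClassification:
    """Classify one neuron's task modulation across the three epochs.

    Four one-sided paired tests, each against the 1 s baseline preceding
    that alignment's event in the same trial: cue-window (0-2 s after tone
    onset, baseline before the tone) separately for high- and low-
    probability cues; post-reward licking (first lick to last lick,
    baseline before the first lick); and 1 s after the end of licking
    (baseline before the last lick).  Anchoring each baseline to its own
    event is what keeps a slowly decaying cue transient from masquerading
    as post-reward activity.  A test is significant at ``alpha / 4``
    (Bonferroni over the four tests); the cue flag is raised when either
    cue condition is significant.  Significance requires an increase from
    baseline.  Conditions with fewer than ``min_trials`` analyzable trials
    leave the classification indeterminate.
    """
    if lick_events is None:
        if licks is None:
            raise ValueError("provide lick_events or licks")
        lick_events = trial_lick_events(trials, licks, gap_threshold_s)
    alpha_adj = alpha / 4.0

    onsets = trials["tone_onset_s"].to_numpy()
    base = np.array(
        [window_mean(trace, frame_rate_hz, t - baseline_s, t) for t in onsets]
    )
    cue_resp = np.array(
        [window_mean(trace, frame_rate_hz, t, t + cue_window_s) for t in onsets]
    )

    p_values: dict[str, float] = {}
    indeterminate = False
    is_high = (trials["cue"] == "high").to_numpy()
    for label, mask in (("cue_high", is_high), ("cue_low", ~is_high)):
        if mask.sum() < min_trials:
            p_values[label] = np.nan
            indeterminate = True
        else:
            p_values[label] = _paired_increase_p(cue_resp[mask], base[mask], test)

    inc = lick_events["included"].to_numpy()
    first = lick_events["first_reward_lick_s"].to_numpy()
    last = lick_events["last_lick_s"].to_numpy()
    lick_resp = np.array(
        [
            window_mean(trace, frame_rate_hz, first[i], max(last[i], first[i] + 0.2))
            if inc[i]
            else np.nan
            for i in range(len(trials))
        ]
    )
    lick_base = np.array(
        [
            window_mean(trace, frame_rate_hz, first[i] - baseline_s, first[i])
            if inc[i]
            else np.nan
            for i in range(len(trials))
        ]
    )
    post_resp = np.array(
        [
            window_mean(trace, frame_rate_hz, last[i], last[i] + postlick_window_s)
            if inc[i]
            else np.nan
            for i in range(len(trials))
        ]
    )
    post_base = np.array(
        [
            window_mean(trace, frame_rate_hz, last[i] - baseline_s, last[i])
            if inc[i]
            else np.nan
            for i in range(len(trials))
        ]
    )
    for label, resp, bas in (
        ("lick", lick_resp, lick_base),
        ("postlick", post_resp, post_base),
    ):
        ok = np.isfinite(resp) & np.isfinite(bas)
        if ok.sum() < min_trials:
            p_values[label] = np.nan
            indeterminate = True
        else:
            p_values[label] = _paired_increase_p(resp[ok], bas[ok], test)

    def sig(*labels: str) -> bool:
        return any(
            np.isfinite(p_values[l]) and p_values[l] < alpha_adj for l in labels
        )

    return EpochClassification(
        neuron_id=neuron_id,
        cue_mod=sig("cue_high", "cue_low"),
        lick_mod=sig("lick"),
        postlick_mod=sig("postlick"),
        p_values=p_values,
        indeterminate=indeterminate,
    )


def classify_population(
    dff: np.ndarray,
    frame_rate_hz: float,
    trials: pd.DataFrame,
    licks: np.ndarray,
    meta: pd.DataFrame | None = None,
    alpha: float = 0.01,
    **kwargs,
) -> pd.DataFrame:
    """Classify every row of a (n_neurons, T) dF/F array; tabulate results."""
    lick_events = trial_lick_events(
        trials, licks, kwargs.get("gap_threshold_s", 1.0)
    )
    records = []
    for j in range(dff.shape[0]):
        c = classify_epochs(
            dff[j],
            frame_rate_hz,
            trials,
            lick_events=lick_events,
            alpha=alpha,
            neuron_id=j,
            **kwargs,
        )
        records.append(
            {
                "neuron_id": j,
                "cue_mod": c.cue_mod,
                "lick_mod": c.lick_mod,
                "postlick_mod": c.postlick_mod,
                "task_mod": c.task_mod,
                "selective_epoch": c.selective_epoch,
                "indeterminate": c.indeterminate,
                **{f"p_{k}": v for k, v in c.p_values.items()},
            }
        )
    out = pd.DataFrame(records)
    if meta is not None:
        out = out.merge(
            meta.reset_index(drop=True).assign(neuron_id=lambda d: d.index)
            if "neuron_id" not in meta.columns
            else meta,
            on="neuron_id",
            how="left",
        )
    return out


# ---------------------------------------------------------------------------
# group fractions
# ---------------------------------------------------------------------------

def fisher_exact_counts(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher's exact p for k1/n1 vs k2/n2."""
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def epoch_fractions(
    classifications: pd.DataFrame,
    group_col: str = "compartment",
    ci_level: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Task-modulated and per-epoch selective fractions with CIs and tests.

    Returns ``(fractions, contrasts)``.  ``fractions`` has one row per
    group x measure (task_mod overall; each selective epoch among the
    task-modulated) with binomial (Clopper-Pearson) confidence intervals.
    ``contrasts`` holds the two-sided Fisher's exact p for every pairwise
    group comparison of each measure.
    """
    groups = list(classifications.groupby(group_col))
    if any(len(df) == 0 for _, df in groups) or not groups:
        raise ValueError("every group must contain at least one neuron")

    rows, counts = [], {}
    for name, df in groups:
        n = len(df)
        task = df["task_mod"]
        measures = {"task_mod": (int(task.sum()), n)}
        tm = df[task]
        for epoch in EPOCH_NAMES:
            measures[f"selective_{epoch}"] = (
                int((tm["selective_epoch"] == epoch).sum()),
                max(len(tm), 1),
            )
        for measure, (k, m) in measures.items():
            ci = stats.binomtest(k, m).proportion_ci(confidence_level=ci_level)
            rows.append(
                {
                    group_col: name,
                    "measure": measure,
                    "count": k,
                    "n": m,
                    "fraction": k / m,
                    "ci_low": ci.low,
                    "ci_high": ci.high,
                }
            )
            counts[(name, measure)] = (k, m)

    contrast_rows = []
    names = [name for name, _ in groups]
    for a, b in combinations(names, 2):
        for measure in ["task_mod"] + [f"selective_{e}" for e in EPOCH_NAMES]:
            k1, n1 = counts[(a, measure)]
            k2, n2 = counts[(b, measure)]
            contrast_rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "measure": measure,
                    "p_fisher": fisher_exact_counts(k1, n1, k2, n2),
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(contrast_rows)


# ---------------------------------------------------------------------------
# peak sorting
# ---------------------------------------------------------------------------

def peak_sort(session_averaged: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Max-normalize rows and order them by peak time (ties by row index).

    All-zero rows are left unnormalized and sorted last.  Returns
    ``(order, normalized_matrix)`` where ``normalized_matrix`` is already
    reordered.
    """
    mat = np.asarray(session_averaged, dtype=float)
    if mat.size == 0:
        raise ValueError("empty response matrix")
    maxima = mat.max(axis=1)
    zero = maxima == 0
    norm = mat.copy()
    norm[~zero] = mat[~zero] / maxima[~zero, None]
    peak_idx = np.argmax(mat, axis=1).astype(float)
    peak_idx[zero] = np.inf  # flat rows go last
    order = np.lexsort((np.arange(mat.shape[0]), peak_idx))
    return order, norm[order]


# ---------------------------------------------------------------------------
# aggregate (neuropil region) responses
# ---------------------------------------------------------------------------

def aggregate_region_response(
    sessions: list[dict],
    tone_window_s: tuple[float, float] = (0.0, 2.0),
    baseline_s: float = 1.0,
) -> dict:
    """Compartment x cue ANOVA on paired striosome/matrix region responses.

    Each session dict must provide ``session_id``, ``trials``,
    ``frame_rate_hz``, and dF/F traces under ``striosome`` and ``matrix``
    (paired regions from the same field of view).  Traces are z-scored to
    the last 1 s of the inter-trial interval (the second before each tone
    onset), the tone-window response is averaged per session x compartment
    x cue, and a repeated-measures ANOVA (subject = session) with factors
    compartment and cue is fit, followed by paired post hoc t-tests.
    """
    from statsmodels.stats.anova import AnovaRM

    rows = []
    for sess in sessions:
        trials = sess["trials"]
        rate = sess["frame_rate_hz"]
        onsets = trials["tone_onset_s"].to_numpy()
        for comp in ("striosome", "matrix"):
            if comp not in sess:
                raise ValueError(f"session {sess.get('session_id')} missing {comp} region")
            trace = np.asarray(sess[comp], dtype=float)
            mean_b, sd_b = pooled_baseline(
                trace, rate, onsets, window_s=(-baseline_s, 0.0)
            )
            z = zscore_trace(trace, mean_b, sd_b)
            resp = np.array(
                [
                    window_mean(z, rate, t + tone_window_s[0], t + tone_window_s[1])
                    for t in onsets
                ]
            )
            for cue in ("high", "low"):
                mask = (trials["cue"] == cue).to_numpy()
                rows.append(
                    {
                        "session_id": sess["session_id"],
                        "compartment": comp,
                        "cue": cue,
                        "response": float(np.nanmean(resp[mask])) if mask.any() else np.nan,
                    }
                )
    table = pd.DataFrame(rows).dropna()
    counts = table.groupby("session_id").size()
    table = table[table["session_id"].isin(counts[counts == 4].index)]
    if table["session_id"].nunique() < 2:
        raise ValueError("need >= 2 complete paired sessions")

    anova = AnovaRM(
        table, depvar="response", subject="session_id", within=["compartment", "cue"]
    ).fit()
    aov = anova.anova_table

    wide = table.pivot_table(
        index="session_id", columns=["compartment", "cue"], values="response"
    )
    posthoc = {}
    for cue in ("high", "low"):
        t, p = stats.ttest_rel(wide[("striosome", cue)], wide[("matrix", cue)])
        posthoc[f"striosome_vs_matrix_{cue}"] = {"t": float(t), "p": float(p)}
    for comp in ("striosome", "matrix"):
        t, p = stats.ttest_rel(wide[(comp, "high")], wide[(comp, "low")])
        posthoc[f"high_vs_low_{comp}"] = {"t": float(t), "p": float(p)}

    return {
        "table": table,
        "anova": aov,
        "p_compartment": float(aov.loc["compartment", "Pr > F"]),
        "p_cue": float(aov.loc["cue", "Pr > F"]),
        "p_interaction": float(aov.loc["compartment:cue", "Pr > F"]),
        "posthoc": posthoc,
    }
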