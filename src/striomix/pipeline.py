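"""End-to-end orchestration: simulate -> extract -> analyze -> report.

``run_pipeline`` executes the stages enabled in the config on one synthetic
"mouse": a block of behavior-only training sessions with paired aggregate
neuropil traces (learning criterion, licking history control, session
regression) plus one post-criterion imaging session of single-neuron traces
(epoch classification, selectivity, temporal specificity, reward-history
modulation).  All artifacts land in the run directory; ``report`` turns a
completed run into a recovery checklist of the headline compartment
contrasts.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, events, extract, history, io, metrics, regress, synthgen
from .config import RunConfig, child_seeds

__all__ = ["run_pipeline", "report", "simulate_training_block", "simulate_imaging_session"]

log = logging.getLogger("striomix")


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        if np.isnan(obj):
            return None
        if np.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {str(k): _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def simulate_training_block(cfg: RunConfig, seeds: list[int]) -> list[dict]:
    """Behavior + paired neuropil-region sessions across training.

    Sessions before the learning-step session have no cue discrimination
    (learning level 0) and weak cue-evoked neuropil responses; later
    sessions are learned.  Per-session jitter couples behavioral
    performance and neural gain, which is what the session regression is
    designed to recover.
    """
    sessions = []
    rng = np.random.default_rng(seeds[0])
    for s in range(cfg.n_behavior_sessions):
        base_level = 0.0 if s < cfg.learning_step_session else 1.0
        level = float(np.clip(base_level + rng.normal(0.0, 0.15), 0.0, 1.2))
        trials = synthgen.generate_task_schedule(
            cfg.trials_per_behavior_session,
            cfg.p_high_cue,
            cfg.p_reward_high,
            cfg.p_reward_low,
            tuple(cfg.iti_range_s),
            seed=seeds[1] + s,
            session_id=f"train{s:02d}",
        )
        licks = synthgen.generate_licking(
            trials,
            learning_level=level,
            anticipatory_rate_high=cfg.anticipatory_rate_high,
            anticipatory_rate_low=cfg.anticipatory_rate_low,
            history_effect=cfg.history_effect,
            bout_rate=cfg.bout_rate,
            bout_duration_s=cfg.bout_duration_s,
            seed=seeds[2] + s,
        )
        gain = 0.25 + 0.75 * level  # neural cue gain tracks performance
        regions = synthgen.generate_region_traces(
            trials,
            licks,
            cue_gain={
                "striosome": (0.30 * gain, 0.18 * gain),
                "matrix": (0.15 * gain, 0.09 * gain),
            },
            seed=seeds[3] + s,
            frame_rate_hz=cfg.frame_rate_hz,
        )
        sessions.append(
            {
                "session_id": f"train{s:02d}",
                "trials": trials,
                "licks": licks,
                "frame_rate_hz": cfg.frame_rate_hz,
                "level": level,
                **regions,
            }
        )
    return sessions


def simulate_imaging_session(cfg: RunConfig, seeds: list[int]) -> dict:
    """One post-criterion single-neuron imaging session."""
    trials = synthgen.generate_task_schedule(
        cfg.n_trials,
        cfg.p_high_cue,
        cfg.p_reward_high,
        cfg.p_reward_low,
        tuple(cfg.iti_range_s),
        seed=seeds[4],
        session_id="imaging",
    )
    licks = synthgen.generate_licking(
        trials,
        learning_level=1.0,
        anticipatory_rate_high=cfg.anticipatory_rate_high,
        anticipatory_rate_low=cfg.anticipatory_rate_low,
        history_effect=cfg.history_effect,
        bout_rate=cfg.bout_rate,
        bout_duration_s=cfg.bout_duration_s,
        seed=seeds[5],
    )
    profile = {k: tuple(v) for k, v in cfg.compartment_gain_profile.items()}
    tuning = synthgen.generate_neurons(
        cfg.n_neurons,
        striosome_fraction=cfg.striosome_fraction,
        epoch_mix=cfg.epoch_mix,
        compartment_gain_profile=profile,
        amplitude_median=cfg.amplitude_median,
        amplitude_sigma_ln=cfg.amplitude_sigma_ln,
        epoch_amplitude_scale=cfg.epoch_amplitude_scale,
        noise_sigma=cfg.noise_sigma,
        seed=seeds[6],
    )
    fluor = synthgen.generate_fluorescence(
        trials, licks, tuning, frame_rate_hz=cfg.frame_rate_hz, seed=seeds[7]
    )
    return {"trials": trials, "licks": licks, "tuning": tuning, "fluor": fluor}


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all enabled stages; write artifacts; return the summary dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(cfg.seed, 12)
    summary: dict = {"seed": cfg.seed, "stages": list(cfg.stages)}
    stage = "setup"
    try:
        # ----------------------------------------------------------- simulate
        stage = "simulate"
        training = simulate_training_block(cfg, seeds)
        imaging = simulate_imaging_session(cfg, seeds)
        if "simulate" in cfg.stages:
            io.write_trials_csv(imaging["trials"], out / "trials.csv")
            io.write_licks_csv(imaging["licks"], out / "licks.csv", "imaging")
            io.write_traces_h5(
                out / "traces.h5",
                imaging["fluor"].f_cell,
                imaging["fluor"].f_ring,
                cfg.frame_rate_hz,
                synthgen.tuning_frame(imaging["tuning"]),
            )

        # ------------------------------------------------------------ extract
        stage = "extract"
        meta = synthgen.tuning_frame(imaging["tuning"])[
            ["neuron_id", "compartment", "tdtomato", "epoch_pref"]
        ]
        dff = extract.traces_to_dff(
            imaging["fluor"].f_cell,
            imaging["fluor"].f_ring,
            cfg.frame_rate_hz,
            meta=meta,
            session_id="imaging",
        )
        if "extract" in cfg.stages:
            dff.meta.to_csv(out / "neurons.csv", index=False)
        summary["extract"] = {
            "n_neurons": int(dff.n_neurons),
            "f0_mean": float(dff.f0.mean()),
            "baseline_dff_mean_pct": float(
                np.mean(
                    [
                        events.window_mean(dff.dff[j], cfg.frame_rate_hz, t - 1.0, t)
                        for j in range(dff.n_neurons)
                        for t in imaging["trials"]["tone_onset_s"].to_numpy()[:40]
                    ]
                )
            ),
        }

        # ------------------------------------------------------------- events
        stage = "events"
        trials, licks = imaging["trials"], imaging["licks"]
        classifications = events.classify_population(
            dff.dff,
            cfg.frame_rate_hz,
            trials,
            licks,
            meta=dff.meta,
            alpha=cfg.alpha,
            test=cfg.epoch_test,
            gap_threshold_s=cfg.gap_threshold_s,
        )
        if "events" in cfg.stages:
            classifications.to_csv(out / "classification.csv", index=False)
        fractions, contrasts = events.epoch_fractions(classifications)
        if "events" in cfg.stages:
            fractions.to_csv(out / "fractions.csv", index=False)
            contrasts.to_csv(out / "fraction_contrasts.csv", index=False)
        region_anova = events.aggregate_region_response(
            [s for s in training if s["level"] > 0.5]
        )
        frac = fractions.set_index(["compartment", "measure"])

        def _f(comp, measure):
            try:
                return float(frac.loc[(comp, measure), "fraction"])
            except KeyError:
                return float("nan")

        cue_counts = {
            comp: int(
                classifications[
                    (classifications["compartment"] == comp)
                    & classifications["cue_mod"]
                ].shape[0]
            )
            for comp in ("striosome", "matrix")
        }
        n_by_comp = classifications.groupby("compartment").size().to_dict()
        summary["events"] = {
            "task_modulated_fraction": {
                comp: _f(comp, "task_mod") for comp in ("striosome", "matrix")
            },
            "cue_modulated_fraction": {
                comp: cue_counts[comp] / n_by_comp[comp]
                for comp in ("striosome", "matrix")
            },
            "p_fisher_task_mod": float(
                contrasts.set_index("measure").loc["task_mod", "p_fisher"]
            ),
            "p_fisher_cue_mod": events.fisher_exact_counts(
                cue_counts["striosome"],
                n_by_comp["striosome"],
                cue_counts["matrix"],
                n_by_comp["matrix"],
            ),
            "region_anova": {
                "p_compartment": region_anova["p_compartment"],
                "p_cue": region_anova["p_cue"],
                "p_interaction": region_anova["p_interaction"],
            },
        }

        # ------------------------------------------------------------ metrics
        if "metrics" in cfg.stages:
            stage = "metrics"
            lick_events = events.trial_lick_events(trials, licks, cfg.gap_threshold_s)
            onsets = trials["tone_onset_s"].to_numpy()
            task_ids = classifications[classifications["task_mod"]][
                "neuron_id"
            ].to_numpy()
            ztraces = {}
            for j in task_ids:
                m, s = events.pooled_baseline(dff.dff[j], cfg.frame_rate_hz, onsets)
                if s > 0:
                    ztraces[j] = events.zscore_trace(dff.dff[j], m, s)

            # cue AUROC on the aggregate neuropil of learned sessions
            cue_auroc = {}
            learned = [s for s in training if s["level"] > 0.5][:5]
            for comp in ("striosome", "matrix"):
                highs, lows = [], []
                for sess in learned:
                    tr = sess["trials"]
                    f0 = extract.estimate_baseline_mode(sess[comp])
                    z = extract.compute_dff(sess[comp], f0)
                    resp = np.array(
                        [
                            events.window_mean(z, cfg.frame_rate_hz, t, t + 2.0)
                            for t in tr["tone_onset_s"]
                        ]
                    )
                    is_high = (tr["cue"] == "high").to_numpy()
                    highs.extend(resp[is_high])
                    lows.extend(resp[~is_high])
                cue_auroc[comp] = metrics.auroc(
                    highs,
                    lows,
                    n_permutations=cfg.n_permutations,
                    seed=seeds[8],
                    contrast="high_vs_low_cue",
                    unit_id=comp,
                )

            # outcome selectivity of task-modulated single neurons
            outcome_rows = []
            for j, z in ztraces.items():
                res = metrics.outcome_selectivity(
                    z,
                    cfg.frame_rate_hz,
                    trials,
                    lick_events,
                    n_permutations=1,  # selectivity value only, skip the permutation p
                    seed=seeds[9],
                    unit_id=j,
                )
                for label, r in res.items():
                    outcome_rows.append(
                        {"neuron_id": j, "cue": label, "auroc": r.auroc}
                    )
            outcome_df = pd.DataFrame(outcome_rows)
            if len(outcome_df):
                outcome_df.to_csv(out / "outcome_selectivity.csv", index=False)

            # cross-neuron shuffle null on post-reward responses
            shuffle_summary = {}
            anchor = lick_events["first_reward_lick_s"].to_numpy()
            aligned = {}
            common = None
            for j, z in ztraces.items():
                a = events.align(
                    z,
                    cfg.frame_rate_hz,
                    anchor,
                    window_s=(0.0, 4.0),
                    trial_ids=trials["trial_id"].to_numpy(),
                    alignment="first_reward_lick",
                )
                aligned[j] = a
                ids = set(a.included_trials.tolist())
                common = ids if common is None else (common & ids)
            if common and len(aligned) >= cfg.shuffle_min_neurons:
                common = sorted(common)
                responses = {
                    j: a.values[np.isin(a.included_trials, common)]
                    for j, a in aligned.items()
                }
                time_axis = next(iter(aligned.values())).time_axis_s
                shuf = metrics.shuffle_across_neurons(
                    responses,
                    time_axis,
                    n_repeats=cfg.shuffle_repeats,
                    min_neurons=cfg.shuffle_min_neurons,
                    seed=seeds[10],
                )
                shuffle_summary = {
                    "observed_reliability": float(
                        shuf["observed"]["reliability"].mean()
                    ),
                    "shuffled_reliability": float(
                        shuf["shuffled"]["reliability"].mean()
                    ),
                    "observed_peak_time_sd_s": float(
                        shuf["observed"]["peak_time_sd_s"].mean()
                    ),
                    "shuffled_peak_time_sd_s": float(
                        shuf["shuffled"]["peak_time_sd_s"].mean()
                    ),
                    "ranksum_p": shuf["ranksum_p"],
                    "mean_field_max_abs_diff": float(
                        np.max(
                            np.abs(
                                shuf["population_mean_field_observed"]
                                - shuf["population_mean_field_shuffled"]
                            )
                        )
                    ),
                }
            summary["metrics"] = {
                "cue_auroc": {
                    comp: {"auroc": r.auroc, "p": r.p_value}
                    for comp, r in cue_auroc.items()
                },
                "outcome_auroc_mean": (
                    float(outcome_df[outcome_df["cue"] == "pooled"]["auroc"].mean())
                    if len(outcome_df)
                    else float("nan")
                ),
                "shuffle": shuffle_summary,
            }

        # ------------------------------------------------------------ history
        if "history" in cfg.stages:
            stage = "history"
            onsets = trials["tone_onset_s"].to_numpy()
            zmat, keep = [], []
            for j in range(dff.n_neurons):
                m, s = events.pooled_baseline(dff.dff[j], cfg.frame_rate_hz, onsets)
                if s > 0:
                    zmat.append(events.zscore_trace(dff.dff[j], m, s))
                    keep.append(j)
            zmat = np.vstack(zmat)
            task_set = set(
                classifications[classifications["task_mod"]]["neuron_id"].tolist()
            )
            rows_mask = [j in task_set for j in keep]
            hmi_df = history.population_hmi(
                zmat[np.asarray(rows_mask)],
                cfg.frame_rate_hz,
                trials,
                meta=None,
            )
            id_map = {
                local: keep[i]
                for local, i in enumerate(np.flatnonzero(rows_mask))
            }
            if len(hmi_df):
                hmi_df["neuron_id"] = hmi_df["neuron_id"].map(id_map)
                hmi_df = hmi_df.merge(
                    dff.meta[["neuron_id", "compartment"]], on="neuron_id", how="left"
                )
                hmi_df.to_csv(out / "hmi.csv", index=False)
            hist_cmp = history.compare_history_effects(hmi_df)
            lick_control = history.licking_history_control(
                [s for s in training if s["level"] > 0.5]
            )
            summary["history"] = {
                "hmi": hist_cmp,
                "licking_control": lick_control,
            }

        # ----------------------------------------------------------- behavior
        if "behavior" in cfg.stages:
            stage = "behavior"
            counts = []
            for sess in training:
                am = behavior.anticipatory_measure(sess["licks"], sess["trials"])
                counts.append(
                    (
                        am[am["cue"] == "high"]["anticipatory_count"].to_numpy(),
                        am[am["cue"] == "low"]["anticipatory_count"].to_numpy(),
                    )
                )
            phases = behavior.learning_criterion(counts, alpha=cfg.alpha_learning)
            phases.to_csv(out / "session_phases.csv", index=False)
            crit = phases[phases["criterion_met"]]
            summary["behavior"] = {
                "criterion_session": (
                    int(crit["session_index"].iloc[0]) if len(crit) else None
                ),
                "n_significant_sessions": int(phases["significant"].sum()),
            }

        # ------------------------------------------------------------ regress
        if "regress" in cfg.stages:
            stage = "regress"
            table = regress.build_session_table(training)
            table.to_csv(out / "regression_table.csv", index=False)
            fits = regress.fit_models(table)
            summary["regress"] = {
                cond: {
                    "striosome_coefficient": fits[cond]["striosome"]["coefficient"],
                    "matrix_coefficient": fits[cond]["matrix"]["coefficient"],
                    "combined_coefficient": fits[cond]["combined"]["coefficient"],
                    "combined_r_squared": fits[cond]["combined"]["r_squared"],
                    "residual_mean_striosome": fits[cond]["combined"][
                        "residual_mean_striosome"
                    ],
                    "residual_mean_matrix": fits[cond]["combined"][
                        "residual_mean_matrix"
                    ],
                    "residual_paired_p": fits[cond]["combined"]["residual_paired_p"],
                }
                for cond in regress.CONDITIONS
            }

        # -------------------------------------------------------------- movie
        if "movie" in cfg.stages:
            stage = "movie"
            sub = imaging["tuning"][: cfg.movie_n_neurons]
            fluor = imaging["fluor"]
            small = synthgen.FluorescenceData(
                f_cell=fluor.f_cell[: len(sub), : cfg.movie_n_frames],
                f_ring=fluor.f_ring[: len(sub), : cfg.movie_n_frames],
                clean=fluor.clean[: len(sub), : cfg.movie_n_frames],
                frame_rate_hz=cfg.frame_rate_hz,
                tuning=list(sub),
            )
            stack = synthgen.generate_movie(
                small,
                field_shape=tuple(cfg.movie_field),
                jitter_amplitude_px=cfg.movie_jitter_px,
                seed=seeds[11],
            )
            io.write_movie_tiff(stack, out / "movie.tiff", out / "movie_masks.json")
            shifts, _ = extract.register_translation(stack)
            summary["movie"] = {
                "n_frames": int(stack.frames.shape[0]),
                "shift_recovery_fraction": float(
                    np.mean(np.all(shifts == stack.true_shifts, axis=1))
                ),
            }
    except Exception as err:  # partial artifacts are retained on failure
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    summary_clean = _round_floats(summary)
    (out / "summary.json").write_text(json.dumps(summary_clean, indent=2, sort_keys=True))
    (out / "run.log").write_text(
        "\n".join(
            [
                f"python {platform.python_version()}",
                f"numpy {np.__version__}",
                f"master_seed {cfg.seed}",
                f"stage_seeds {seeds}",
            ]
        )
    )
    cfg.to_yaml(out / "config.yaml")
    return summary_clean


def report(run_dir) -> dict:
    """Recovery checklist for a completed (or partial) run directory."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary.json under {run_dir}")
    summary = json.loads(summary_path.read_text())
    checklist = {}

    ev = summary.get("events")
    if ev:
        cf = ev["cue_modulated_fraction"]
        checklist["striosome_cue_fraction_exceeds_matrix"] = {
            "pass": cf["striosome"] > cf["matrix"],
            "striosome": cf["striosome"],
            "matrix": cf["matrix"],
            "p_fisher": ev["p_fisher_cue_mod"],
        }
    else:
        checklist["striosome_cue_fraction_exceeds_matrix"] = {"pass": None, "note": "not run"}

    hi = summary.get("history", {}).get("hmi")
    if hi and "group_means" in hi:
        gm = hi["group_means"]
        ok = (
            "striosome" in gm
            and "matrix" in gm
            and abs(gm["matrix"]) > abs(gm["striosome"])
        )
        checklist["matrix_hmi_magnitude_exceeds_striosome"] = {
            "pass": bool(ok),
            "mean_hmi": gm,
            "p_ranksum": hi.get("p_compartment_ranksum"),
        }
    else:
        checklist["matrix_hmi_magnitude_exceeds_striosome"] = {"pass": None, "note": "not run"}

    sh = summary.get("metrics", {}).get("shuffle")
    if sh:
        checklist["shuffle_degrades_reliability"] = {
            "pass": sh["observed_reliability"] > sh["shuffled_reliability"],
            "observed": sh["observed_reliability"],
            "shuffled": sh["shuffled_reliability"],
        }
    else:
        checklist["shuffle_degrades_reliability"] = {"pass": None, "note": "not run"}

    be = summary.get("behavior")
    if be:
        checklist["learning_criterion_detected"] = {
            "pass": be["criterion_session"] is not None,
            "criterion_session": be["criterion_session"],
        }
    else:
        checklist["learning_criterion_detected"] = {"pass": None, "note": "not run"}

    n_pass = sum(1 for v in checklist.values() if v.get("pass") is True)
    out = {"checklist": checklist, "n_pass": n_pass, "n_items": len(checklist)}
    (run_dir / "report.json").write_text(json.dumps(_round_floats(out), indent=2, sort_keys=True))
    return out
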