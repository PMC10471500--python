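"""End-to-end orchestration: simulate/load -> behavior -> ephys -> decode -> lag.

``run_pipeline`` executes every stage on one logical session and writes a
JSON report of psychometric fits, unit statistics, decoding accuracy
timecourses and inter-region lags, together with the resolved
configuration and all seeds, so a rerun with the same seed reproduces the
report byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, decoding, ephys, lag, synth
from .io import PipelineConfig, read_tables, write_tables


def _session_from_config(config: PipelineConfig) -> synth.Session:
    if config.trials_path is not None:
        trials, events, spikes, units = read_tables(
            config.trials_path, config.events_path,
            config.spikes_path, config.units_path)
        sid = str(trials["session_id"].iloc[0]) if len(trials) else "s0"
        rat = str(trials["rat_id"].iloc[0]) if len(trials) else "rat0"
        return synth.Session(sid, rat, trials, events, spikes, units,
                             synth.SimConfig(), None)
    sim_cfg = replace(synth.SimConfig(rng_seed=config.seed), **config.sim)
    return synth.gen_session(sim_cfg)


def behavior_stage(trials: pd.DataFrame) -> dict:
    flagged = behavior.filter_trials(trials)
    kept = flagged.loc[~flagged["excluded"]]
    fit = behavior.fit_psychometric(kept)
    rel = behavior.relative_latency(kept)
    out = {
        "n_trials": int(len(trials)),
        "n_excluded": int(flagged["excluded"].sum()),
        "exclusions_by_reason": behavior.exclusion_counts(flagged),
        "beta0": round(fit.beta0, 6),
        "beta1": round(fit.beta1, 6),
        "accuracy": round(fit.accuracy, 6),
        "preference_score": (None if fit.preference_undefined
                             else round(fit.preference_score, 6)),
        "separation_fallback": fit.separation_fallback,
        "relative_latency": {f"{k[0]}v{k[1]}": round(v, 6)
                             for k, v in rel.items()},
    }
    return out


def ephys_stage(session: synth.Session, config: PipelineConfig,
                fit: behavior.PsychometricFit, kept: pd.DataFrame) -> dict:
    duration = float(session.spikes["spike_time"].max() + 1.0)
    report = {}
    tensors = {}
    ev_kept = session.events.set_index("trial_id").loc[
        kept["trial_id"]].reset_index()
    regions = sorted(session.units["region"].unique())
    stats_list = []
    for region in regions:
        uids = session.units.loc[session.units["region"] == region,
                                 "unit_id"].to_numpy()
        sub = session.spikes[session.spikes["unit_id"].isin(uids)]
        binned = ephys.bin_and_zscore(sub, duration, unit_ids=uids,
                                      bin_width=config.bin_width,
                                      bin_step=config.bin_step)
        tensor = ephys.align_and_baseline(binned, ev_kept, "cue_onset",
                                          window=(-0.5, 5.0))
        tensors[region] = (binned, tensor)
        st = ephys.detect_task_modulation(tensor, alpha=config.alpha)
        x = ephys.build_task_variables(kept, fit=fit)
        st = ephys.tuning_regression(tensor, x,
                                     response_window=config.response_window,
                                     alpha=config.alpha, stats_in=st)
        stats_list.append(st)
        report[region] = {
            "n_units": int(len(uids)),
            "n_task_modulated": int(st.task_modulated.sum()),
        }
    props = ephys.modulation_proportions(stats_list, regions)
    report["modulation_proportions"] = {
        r: {k: round(float(v), 6) for k, v in row.items()}
        for r, row in props.iterrows()}
    return report, tensors, ev_kept


def decode_stage(session: synth.Session, config: PipelineConfig,
                 tensors: dict, ev_kept: pd.DataFrame,
                 kept: pd.DataFrame) -> dict:
    regions = sorted(tensors)
    labels = np.where(kept["chosen_side"].to_numpy() == "right", 1, -1)
    correct = synth.is_correct_choice(kept)
    half = config.lag_window / 2.0
    report = {}
    lag_inputs = {}
    for region in regions:
        binned, cue_tensor = tensors[region]
        res = decoding.train_eval_timecourse(
            cue_tensor.values, labels, times=cue_tensor.times,
            C=config.svm_c, n_repeats=config.n_repeats, k=config.n_folds,
            seed=config.seed)
        np_tensor = ephys.align_and_baseline(
            binned, ev_kept, "choice_nosepoke", window=(-half, half))
        cp = decoding.choice_parameter(
            np_tensor.values, labels, times=np_tensor.times, C=config.svm_c,
            n_repeats=config.n_repeats, k=config.n_folds, seed=config.seed)
        lag_inputs[region] = cp
        rise = lag.threshold_latency(
            np.clip(res.accuracy - 0.5, 0, None), res.times,
            threshold=config.threshold)
        report[region] = {
            "peak_accuracy": round(float(res.accuracy.max()), 6),
            "mean_accuracy": round(float(res.accuracy.mean()), 6),
            "rise_latency_s": None if np.isnan(rise) else round(rise, 6),
        }
    report["regions"] = regions
    return report, lag_inputs, correct


def lag_stage(session: synth.Session, config: PipelineConfig,
              lag_inputs: dict, correct: np.ndarray,
              eligible: np.ndarray | None = None) -> dict:
    regions = sorted(lag_inputs)
    if len(regions) != 2:
        return {"skipped": f"need 2 regions, found {len(regions)}"}
    cp1 = lag_inputs[regions[0]].values
    cp2 = lag_inputs[regions[1]].values
    res = lag.session_lag(cp1, cp2, correct, eligible=eligible,
                          session_id=session.session_id,
                          dt=config.bin_step, sigma=config.smooth_sigma,
                          max_lag=config.max_lag)
    def _num(v):
        return None if not np.isfinite(v) else round(float(v), 6)
    return {
        "lag_correct_s": _num(res.lag_correct),
        "lag_incorrect_s": _num(res.lag_incorrect),
        "n_correct": res.n_correct,
        "n_incorrect": res.n_incorrect,
    }


def run_pipeline(config: PipelineConfig, outdir=None,
                 behavior_only: bool = False) -> dict:
    """Run all stages on one session and return (and optionally write) the report."""
    report: dict = {"seed": config.seed}
    stage = "simulate/load"
    try:
        session = _session_from_config(config)
        report["session_id"] = session.session_id

        stage = "behavior"
        flagged = behavior.filter_trials(session.trials)
        kept = flagged.loc[~flagged["excluded"]].reset_index(drop=True)
        report["behavior"] = behavior_stage(session.trials)
        fit = behavior.fit_psychometric(kept)

        if session.spikes is None or behavior_only:
            report["note"] = "behavior-only run (no spike data)"
        else:
            stage = "ephys"
            ephys_rep, tensors, ev_kept = ephys_stage(session, config, fit,
                                                      kept)
            report["ephys"] = ephys_rep
            stage = "decode"
            dec_rep, lag_inputs, correct = decode_stage(
                session, config, tensors, ev_kept, kept)
            report["decoding"] = dec_rep
            stage = "lag"
            eligible = behavior.delta_drops(kept) != 0
            report["lag"] = lag_stage(session, config, lag_inputs, correct,
                                      eligible)
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        config.to_yaml(outdir / "resolved_config.yaml")
        if config.trials_path is None:
            write_tables(outdir / "tables", session.trials, session.events,
                         session.spikes, session.units)
    return report
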