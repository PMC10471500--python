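"""Parameter-recovery experiments validating every pipeline stage.

Each function runs a self-contained simulation-plus-analysis experiment
against the ground truth of the synthetic generator: psychometric
preference recovery, null calibration of the task-modulation and tuning
screens, chance/power calibration of the decoder, and inter-region lag
recovery.  The test suite and the acceptance script both drive these, so
the study conditions live in one place.

Lag sign convention note: the generator's ``region_lag`` L delays region
2's chosen-side onset, so region 1 leads and the analysis recovers a lag
of approximately -L (negative = region 1 leads).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import behavior, decoding, ephys, lag, synth


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed).spawn(n)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss]


# ---------------------------------------------------------------- behavior


def hand_fixture_trials() -> pd.DataFrame:
    """10-trial hand-written fixture with known filter/accuracy counts.

    Trial 4 has a 12.5-s response latency and trial 3 a 5.5-s collection
    latency (the two filter violations); of the 7 retained unequal-offer
    trials exactly one (the last, choosing a 0-drop over a 1-drop offer)
    picks the smaller reward, so accuracy is 6/7.
    """
    offers = [(3, 1), (1, 3), (2, 2), (0, 3), (3, 0),
              (1, 2), (2, 1), (3, 2), (1, 0), (0, 1)]
    chosen = ["blackcurrant", "lemon", "lemon", "lemon", "blackcurrant",
              "lemon", "blackcurrant", "blackcurrant", "blackcurrant",
              "blackcurrant"]
    resp = [1.0, 0.8, 1.2, 0.9, 12.5, 1.1, 0.7, 1.3, 0.6, 1.0]
    coll = [1.0, 1.2, 0.9, 5.5, 1.1, 1.0, 0.8, 1.3, 0.7, 0.9]
    rows = []
    for i, ((b, l), ch) in enumerate(zip(offers, chosen)):
        side = "left" if i % 2 == 0 else "right"
        rows.append({
            "trial_id": i, "session_id": "s0", "rat_id": "r0",
            "blackcurrant_drops": b, "lemon_drops": l,
            "blackcurrant_side": side,
            "chosen_flavor": ch,
            "chosen_side": side if ch == "blackcurrant"
                           else ("right" if side == "left" else "left"),
            "response_latency": resp[i], "collection_latency": coll[i],
            "condition": "baseline",
        })
    return pd.DataFrame(rows)


def preference_recovery(n_sims: int = 100, n_trials: int = 2000,
                        seed: int = 0) -> pd.DataFrame:
    """Fit simulated choice behavior and compare with the generating probit.

    Draws (b0, b1) uniformly from [-1, 1] x [0.5, 3], simulates ``n_trials``
    choices, fits the psychometric model and records the absolute error of
    the recovered preference score (PSE) in drops.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in _child_seeds(seed, n_sims):
        b0 = float(rng.uniform(-1, 1))
        b1 = float(rng.uniform(0.5, 3))
        cfg = synth.SimConfig(n_trials=n_trials, probit_intercept=b0,
                              probit_slope=b1, p_violation=0.0, rng_seed=s)
        trials = synth.gen_choices(synth.gen_trials(cfg), cfg)
        fit = behavior.fit_psychometric(trials)
        rows.append({
            "true_b0": b0, "true_b1": b1,
            "true_pse": -b0 / b1,
            "fit_b0": fit.beta0, "fit_b1": fit.beta1,
            "fit_pse": fit.preference_score,
            "abs_pse_error": abs(fit.preference_score - (-b0 / b1)),
        })
    return pd.DataFrame(rows)


def grid_search_probit(delta: np.ndarray, chose_bc: np.ndarray,
                       b0_range=(-5.0, 5.0), b1_range=(-5.0, 5.0),
                       n_grid: int = 41, n_refine: int = 6,
                       ) -> tuple[float, float]:
    """Coarse-to-fine likelihood grid search for the probit coefficients.

    Independent of the fitting path; used as the MLE oracle.
    """
    y = np.asarray(chose_bc, dtype=float)
    delta = np.asarray(delta, dtype=float)

    def nll(b0, b1):
        eta = b0 + b1 * delta
        return -np.sum(y * norm.logcdf(eta) + (1 - y) * norm.logcdf(-eta))

    lo0, hi0 = b0_range
    lo1, hi1 = b1_range
    for _ in range(n_refine):
        g0 = np.linspace(lo0, hi0, n_grid)
        g1 = np.linspace(lo1, hi1, n_grid)
        vals = np.array([[nll(a, b) for b in g1] for a in g0])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        step0 = g0[1] - g0[0]
        step1 = g1[1] - g1[0]
        lo0, hi0 = g0[i] - step0, g0[i] + step0
        lo1, hi1 = g1[j] - step1, g1[j] + step1
        best = (float(g0[i]), float(g1[j]))
    return best


# ------------------------------------------------------------------ ephys


def null_unit_calibration(n_units: int = 200, n_trials: int = 100,
                          seed: int = 0) -> dict:
    """False-flag rates of both unit screens on homogeneous-Poisson units.

    Simulates a session whose units carry no event or task modulation at
    all, runs the task-modulation and tuning screens, and reports the
    fraction of units flagged by each (expected ~ the corrected alpha).
    """
    cfg = synth.SimConfig(
        n_trials=n_trials, n_units_per_region=n_units // 2,
        kernels={}, tuning_gains={}, p_violation=0.0, rng_seed=seed)
    ses = synth.gen_session(cfg)
    kept = ses.trials
    ev = ses.events
    dur = float(ses.spikes["spike_time"].max() + 1.0)
    binned = ephys.bin_and_zscore(ses.spikes, dur,
                                  unit_ids=ses.units["unit_id"].to_numpy())
    tensor = ephys.align_and_baseline(binned, ev, "cue_onset",
                                      window=(-0.5, 5.0))
    st = ephys.detect_task_modulation(tensor)
    kept_idx = kept["trial_id"].isin(tensor.trial_ids)
    fit = behavior.fit_psychometric(kept.loc[kept_idx])
    x = ephys.build_task_variables(kept.loc[kept_idx], fit=fit)
    st = ephys.tuning_regression(tensor, x, stats_in=st)
    n_tests = np.isfinite(st.slope_p).sum()
    return {
        "n_units": int(len(st.unit_ids)),
        "task_modulated_rate": float(st.task_modulated.mean()),
        "tuning_flag_rate": float(np.nansum(st.tuned) / max(n_tests, 1)),
        "n_tuning_tests": int(n_tests),
    }


# --------------------------------------------------------------- decoding


def _session_tensors(ses: synth.Session, event: str,
                     window: tuple[float, float]):
    flagged = behavior.filter_trials(ses.trials)
    kept = flagged.loc[~flagged["excluded"]].reset_index(drop=True)
    ev = ses.events.set_index("trial_id").loc[kept["trial_id"]].reset_index()
    dur = float(ses.spikes["spike_time"].max() + 1.0)
    tensors = {}
    for region in sorted(ses.units["region"].unique()):
        uids = ses.units.loc[ses.units["region"] == region,
                             "unit_id"].to_numpy()
        sub = ses.spikes[ses.spikes["unit_id"].isin(uids)]
        binned = ephys.bin_and_zscore(sub, dur, unit_ids=uids)
        tensors[region] = ephys.align_and_baseline(binned, ev, event,
                                                   window=window)
    kept_ids = tensors[next(iter(tensors))].trial_ids
    kept = kept[kept["trial_id"].isin(kept_ids)].reset_index(drop=True)
    labels = np.where(kept["chosen_side"].to_numpy() == "right", 1, -1)
    return tensors, kept, labels


def decoding_calibration(n_trials: int = 200, n_units: int = 24,
                         seed: int = 0, n_repeats: int = 5,
                         side_gain_hz: float = 6.0) -> dict:
    """Chance and power calibration of the time-resolved decoder.

    On one strongly side-tuned synthetic session (``side_gain_hz`` per
    unit), decodes chosen side from cue-aligned activity twice: with
    labels shuffled independently per repeat (expected at chance
    everywhere) and with true labels (expected high once the chosen-side
    coding is on).
    """
    cfg = synth.SimConfig(n_trials=n_trials, n_units_per_region=n_units,
                          p_violation=0.0, rng_seed=seed,
                          tuning_gains={"chosen_side": side_gain_hz,
                                        "left_size": 1.0, "right_size": 1.0})
    ses = synth.gen_session(cfg)
    tensors, kept, labels = _session_tensors(ses, "cue_onset", (-0.5, 5.0))
    tensor = tensors["region1"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        shuf = decoding.train_eval_timecourse(
            tensor.values, labels, times=tensor.times, seed=seed,
            n_repeats=n_repeats, shuffle_labels=True)
        true = decoding.train_eval_timecourse(
            tensor.values, labels, times=tensor.times, seed=seed,
            n_repeats=n_repeats)
    onset = cfg.tuning_onset
    # chosen-side coding is on from onset until ~nosepoke + 0.5 s, which
    # varies by trial; assess power at its common-support peak
    post = (true.times >= onset) & (true.times <= onset + 0.75)
    return {
        "times": true.times,
        "shuffled_accuracy": shuf.accuracy,
        "true_accuracy": true.accuracy,
        "n_test_trials": len(labels),
        "post_onset_accuracy": float(true.accuracy[post].max()),
        "pre_cue_accuracy": float(true.accuracy[true.times < 0].mean()),
    }


# -------------------------------------------------------------------- lag


def session_lag_estimate(region_lag: float, seed: int,
                         n_trials: int = 150, n_units: int = 24,
                         n_repeats: int = 5,
                         region_lag_incorrect: float | None = None,
                         ) -> lag.LagResult:
    """Simulate one two-region session and recover its class lags."""
    cfg = synth.SimConfig(n_trials=n_trials, n_units_per_region=n_units,
                          region_lag=region_lag,
                          region_lag_incorrect=region_lag_incorrect,
                          rng_seed=seed)
    ses = synth.gen_session(cfg)
    tensors, kept, labels = _session_tensors(ses, "choice_nosepoke",
                                             (-1.5, 1.5))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cps = {region: decoding.choice_parameter(
                   t.values, labels, times=t.times, n_repeats=n_repeats,
                   seed=seed)
               for region, t in tensors.items()}
    correct = synth.is_correct_choice(kept)
    eligible = behavior.delta_drops(kept) != 0
    return lag.session_lag(cps["region1"].values, cps["region2"].values,
                           correct, eligible=eligible,
                           session_id=ses.session_id)


def lag_recovery(lags_s, n_sessions: int = 20, seed: int = 0,
                 n_trials: int = 150, n_units: int = 24,
                 n_repeats: int = 5) -> pd.DataFrame:
    """Recover injected inter-region lags over seeded session cohorts.

    For each injected lag L, simulates ``n_sessions`` sessions and records
    the recovered correct-class session lag; the expected recovered value
    is -L (region 1 leads when L > 0).
    """
    rows = []
    for L in lags_s:
        for s in _child_seeds(seed + int(round(L * 1e4)) % 9973, n_sessions):
            res = session_lag_estimate(L, s, n_trials=n_trials,
                                       n_units=n_units, n_repeats=n_repeats)
            rows.append({"true_lag": L, "expected": -L,
                         "recovered": res.lag_correct,
                         "n_correct": res.n_correct})
    return pd.DataFrame(rows)


def paired_t_power(n_cohorts: int = 50, n_sessions: int = 30,
                   separation_s: float = 0.07, noise_sd_s: float = 0.03,
                   seed: int = 0, alpha: float = 0.01) -> dict:
    """Power of the correct-vs-incorrect paired comparison on lag values.

    Session lags are drawn directly from the lag-value model (class means
    separated by ``separation_s``, between-session noise ``noise_sd_s``),
    mirroring the session-level statistics, and the fraction of cohorts
    with a paired-t p below ``alpha`` is reported.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_cohorts):
        lc = rng.normal(-separation_s / 2, noise_sd_s, n_sessions)
        li = rng.normal(+separation_s / 2, noise_sd_s, n_sessions)
        results = [lag.LagResult("", c, i, 1, 1, np.empty(0), np.empty(0),
                                 np.empty(0))
                   for c, i in zip(lc, li)]
        cmp = lag.compare_lags(results)
        hits += cmp.p_value < alpha
    return {"power": hits / n_cohorts, "n_cohorts": n_cohorts,
            "alpha": alpha}
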