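"""Synthetic two-alternative economic-choice sessions with known ground truth.

Generates the full data bundle the analysis pipeline consumes — a trial
table, per-trial event times, and two simultaneously recorded populations
of spiking units — from a generative model whose parameters (probit choice
behavior, flavor preference, task tuning, inter-region encoding lag) are
known exactly, so every downstream stage can be validated by parameter
recovery.

Task structure emulated: on each trial two visual cues offer 0-3 drops of
blackcurrant- and lemon-flavored water (the all-zero pair never occurs,
giving 15 offer combinations); the flavor-to-side assignment is randomized
per trial; a mandatory 2-s cue period precedes the choice nosepoke; reward
follows after a fixed handling delay; inter-trial intervals are uniform
5-10 s.  Choices follow a probit model in the drop difference
delta = blackcurrant - lemon, so the simulated point of subjective
equality is -intercept/slope.  Spiking is an inhomogeneous Poisson process
whose rate is a rectified sum of a baseline, boxcar event kernels, and
linear task-variable tuning; chosen-side tuning in region 2 switches on
`region_lag` seconds later than in region 1.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

CUE_PERIOD_S = 2.0          # mandatory cue presentation period
RESPONSE_LIMIT_S = 12.0     # filter bound: slower responses are excluded
COLLECTION_LIMIT_S = 5.0    # filter bound: slower reward collection excluded

#: Default task-variable set; mirrors the analysis module's regressors so
#: tuning recovery is closed-loop (see econphys.ephys.build_task_variables).
TASK_VARIABLES = (
    "left_size",
    "right_size",
    "chosen_side",
    "chosen_flavor",
    "chosen_size",
    "unchosen_size",
    "size_sum",
    "size_diff",
    "left_subjective_value",
    "right_subjective_value",
)


@dataclass
class Kernel:
    """Boxcar firing-rate kernel attached to a task event."""

    amplitude_hz: float
    onset_s: float
    duration_s: float


@dataclass
class SimConfig:
    """Parameters of one simulated session.

    Identical config + seed produces byte-identical outputs.
    """

    n_trials: int = 600
    drop_sizes: tuple[int, ...] = (0, 1, 2, 3)
    flavors: tuple[str, str] = ("blackcurrant", "lemon")
    # Choice model: P(choose blackcurrant) = Phi(b0 + b1 * delta), delta in drops.
    # Slope 0.6/drop yields ~82% choose-larger accuracy over the 15-combination
    # layout; intercept 0.3 gives a mild blackcurrant preference (PSE = -0.5).
    probit_intercept: float = 0.3
    probit_slope: float = 0.6
    latency_base: float = 1.0       # s, mean response latency at delta = 0
    latency_slope: float = 0.15     # s per drop of |delta|
    latency_noise_sd: float = 0.25  # s
    p_violation: float = 0.02       # probability of a filter-violating trial
    handling_delay: float = 0.5     # s, nosepoke -> reward delivery
    iti_range: tuple[float, float] = (5.0, 10.0)
    # Spiking model
    n_units_per_region: int = 24
    baseline_rate: float = 5.0      # Hz
    kernels: dict = field(default_factory=lambda: {
        "cue_onset": Kernel(3.0, 0.0, 0.5),
        "choice_nosepoke": Kernel(3.0, 0.0, 0.5),
        "reward_delivery": Kernel(3.0, 0.0, 0.5),
    })
    # Hz per unit of variable; each tuned unit gets a random +/- sign.
    tuning_gains: dict = field(default_factory=lambda: {
        "chosen_side": 3.0,
        "left_size": 1.0,
        "right_size": 1.0,
    })
    tuned_fraction: float = 1.0
    # Chosen-side coding switches on late in the trial, shortly before the
    # typical nosepoke (cue + 2 s + ~1 s latency), so the onset transition
    # falls inside the 3-s lag-analysis window around the choice.
    tuning_onset: float = 2.5       # s after cue: chosen-side coding onset, region 1
    region_lag: float = 0.05        # s added to region-2 chosen-side onset
    region_lag_incorrect: float | None = None  # per-class lag for error trials
    sim_dt: float = 0.005           # s, rate-discretization step for Poisson draws
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if any(s < 0 for s in self.drop_sizes):
            raise ValueError("drop_sizes must be non-negative")
        if not 0.0 <= self.p_violation <= 1.0:
            raise ValueError("p_violation must be in [0, 1]")
        if not 0.0 <= self.tuned_fraction <= 1.0:
            raise ValueError("tuned_fraction must be in [0, 1]")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be non-negative")
        for name, k in self.kernels.items():
            if k.duration_s < 0:
                raise ValueError(f"kernel {name!r} has negative duration")


@dataclass
class GroundTruth:
    """Recovery bookkeeping: the latent quantities the pipeline estimates."""

    true_preference: float          # drops; the delta at simulated indifference
    true_lag: float                 # s; region-2 minus region-1 coding onset
    tuned_unit_ids: dict            # variable -> array of tuned unit ids
    p_choose_blackcurrant: np.ndarray  # per-trial latent choice probability


@dataclass
class Session:
    """One simulated session: the four tables plus its ground truth."""

    session_id: str
    rat_id: str
    trials: pd.DataFrame
    events: pd.DataFrame
    spikes: pd.DataFrame
    units: pd.DataFrame
    config: SimConfig
    truth: GroundTruth


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def gen_trials(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw offer pairs and side assignments for one session.

    Each trial offers one blackcurrant size and one lemon size drawn
    uniformly from all drop-size pairs excluding the all-zero pair (15
    combinations under the default 0-3 layout); the blackcurrant cue side
    is randomized per trial.
    """
    config.validate()
    rng = rng if rng is not None else _rng(config.rng_seed)
    sizes = np.asarray(config.drop_sizes)
    pairs = [(b, l) for b in sizes for l in sizes if not (b == 0 and l == 0)]
    idx = rng.integers(0, len(pairs), size=config.n_trials)
    bc = np.array([pairs[i][0] for i in idx])
    lem = np.array([pairs[i][1] for i in idx])
    bc_side = np.where(rng.random(config.n_trials) < 0.5, "left", "right")
    return pd.DataFrame({
        "trial_id": np.arange(config.n_trials),
        "blackcurrant_drops": bc,
        "lemon_drops": lem,
        "blackcurrant_side": bc_side,
    })


def gen_choices(trials: pd.DataFrame, config: SimConfig,
                rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate choices, latencies and filter violations for given offers.

    Choice ~ Bernoulli(Phi(b0 + b1*delta)); response latency decreases
    linearly with |delta| plus Gaussian noise, truncated at zero; with
    probability ``p_violation`` the trial violates one of the exclusion
    filters (response latency > 12 s or collection latency > 5 s).
    """
    config.validate()
    if "blackcurrant_drops" not in trials.columns:
        raise ValueError("trials must carry offers; run gen_trials first")
    rng = rng if rng is not None else _rng(config.rng_seed + 1)
    out = trials.copy()
    delta = out["blackcurrant_drops"].to_numpy() - out["lemon_drops"].to_numpy()
    p_bc = norm.cdf(config.probit_intercept + config.probit_slope * delta)
    chose_bc = rng.random(len(out)) < p_bc
    out["chosen_flavor"] = np.where(chose_bc, "blackcurrant", "lemon")
    bc_side = out["blackcurrant_side"].to_numpy()
    other = np.where(bc_side == "left", "right", "left")
    out["chosen_side"] = np.where(chose_bc, bc_side, other)

    lat = (config.latency_base - config.latency_slope * np.abs(delta)
           + rng.normal(0.0, config.latency_noise_sd, len(out)))
    out["response_latency"] = np.clip(lat, 0.0, None)
    out["collection_latency"] = np.clip(
        0.5 + rng.exponential(0.5, len(out)), 0.05, None)

    violate = rng.random(len(out)) < config.p_violation
    slow_response = rng.random(len(out)) < 0.5
    resp_viol = violate & slow_response
    coll_viol = violate & ~slow_response
    out.loc[resp_viol, "response_latency"] = (
        RESPONSE_LIMIT_S + rng.exponential(2.0, int(resp_viol.sum())))
    out.loc[coll_viol, "collection_latency"] = (
        COLLECTION_LIMIT_S + rng.exponential(1.0, int(coll_viol.sum())))

    out["condition"] = "baseline"
    return out


def _event_table(trials: pd.DataFrame, config: SimConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Lay trials out on the session clock: cue, nosepoke, reward times."""
    n = len(trials)
    iti = rng.uniform(*config.iti_range, size=n)
    cue = np.empty(n)
    t = 1.0  # session starts 1 s before the first cue
    resp = trials["response_latency"].to_numpy()
    coll = trials["collection_latency"].to_numpy()
    for i in range(n):
        cue[i] = t
        t = (cue[i] + CUE_PERIOD_S + resp[i] + config.handling_delay
             + coll[i] + iti[i])
    nosepoke = cue + CUE_PERIOD_S + resp
    reward = nosepoke + config.handling_delay
    return pd.DataFrame({
        "trial_id": trials["trial_id"].to_numpy(),
        "cue_onset": cue,
        "choice_nosepoke": nosepoke,
        "reward_delivery": reward,
    })


def trial_variables(trials: pd.DataFrame, preference: float) -> pd.DataFrame:
    """Per-trial values of the ten task variables (generator-side copy).

    Sides are encoded left = -1 / right = +1; flavors blackcurrant = +1 /
    lemon = -1.  Subjective value adds the preference score (in
    blackcurrant-drop units) to lemon offers only.
    """
    bc = trials["blackcurrant_drops"].to_numpy(dtype=float)
    lem = trials["lemon_drops"].to_numpy(dtype=float)
    bc_left = trials["blackcurrant_side"].to_numpy() == "left"
    left = np.where(bc_left, bc, lem)
    right = np.where(bc_left, lem, bc)
    chose_bc = trials["chosen_flavor"].to_numpy() == "blackcurrant"
    chosen_side = np.where(trials["chosen_side"].to_numpy() == "right", 1.0, -1.0)
    chosen = np.where(chose_bc, bc, lem)
    unchosen = np.where(chose_bc, lem, bc)
    lem_subj = lem + preference
    return pd.DataFrame({
        "left_size": left,
        "right_size": right,
        "chosen_side": chosen_side,
        "chosen_flavor": np.where(chose_bc, 1.0, -1.0),
        "chosen_size": chosen,
        "unchosen_size": unchosen,
        "size_sum": bc + lem,
        "size_diff": left - right,
        "left_subjective_value": np.where(bc_left, bc, lem_subj),
        "right_subjective_value": np.where(bc_left, lem_subj, bc),
    })


def gen_spikes(trials: pd.DataFrame, config: SimConfig,
               rng: np.random.Generator | None = None,
               events: pd.DataFrame | None = None,
               ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Simulate two regions of inhomogeneous-Poisson units for one session.

    Each unit's instantaneous rate is ``rectify(baseline + event kernels +
    sum_v gain_uv * x_v)``.  Chosen-side tuning switches on at
    ``cue + tuning_onset`` in region 1 and ``region_lag`` seconds later in
    region 2 (optionally a different lag on incorrect trials); the other
    tuned variables modulate rate throughout the 2-s cue period.

    Returns (spikes, units, events, tuned_unit_ids).
    """
    config.validate()
    rng = rng if rng is not None else _rng(config.rng_seed + 2)
    if events is None:
        events = _event_table(trials, config, rng)

    n_per = config.n_units_per_region
    n_units = 2 * n_per
    unit_ids = np.arange(n_units)
    regions = np.array(["region1"] * n_per + ["region2"] * n_per)

    pref = true_preference(config)
    x = trial_variables(trials, pref)

    # Per-unit tuning: random subset tuned per variable, random +/- sign.
    gains = np.zeros((n_units, len(TASK_VARIABLES)))
    tuned_ids: dict[str, np.ndarray] = {}
    for j, var in enumerate(TASK_VARIABLES):
        g = config.tuning_gains.get(var, 0.0)
        if g == 0.0:
            tuned_ids[var] = np.array([], dtype=int)
            continue
        n_tuned = int(round(config.tuned_fraction * n_per))
        chosen = np.concatenate([
            rng.choice(n_per, size=n_tuned, replace=False),
            n_per + rng.choice(n_per, size=n_tuned, replace=False),
        ])
        signs = rng.choice([-1.0, 1.0], size=chosen.size)
        gains[chosen, j] = g * signs
        tuned_ids[var] = np.sort(chosen)

    dt = config.sim_dt
    duration = float(events["reward_delivery"].iloc[-1]
                     + trials["collection_latency"].iloc[-1] + 2.0)
    n_bins = int(np.ceil(duration / dt))
    rate = np.full((n_units, n_bins), config.baseline_rate)

    def add_box(lo: float, hi: float, amp: np.ndarray | float) -> None:
        i0 = max(int(np.floor(lo / dt)), 0)
        i1 = min(int(np.ceil(hi / dt)), n_bins)
        if i1 > i0:
            rate[:, i0:i1] += np.asarray(amp).reshape(-1, 1)

    cue = events["cue_onset"].to_numpy()
    nosepoke = events["choice_nosepoke"].to_numpy()
    ev_times = {name: events[name].to_numpy() for name in config.kernels}
    correct = is_correct_choice(trials)
    side_j = TASK_VARIABLES.index("chosen_side")
    lag_incorrect = (config.region_lag if config.region_lag_incorrect is None
                     else config.region_lag_incorrect)
    X = x.to_numpy()
    contrib_all = X @ gains.T                      # (trial, unit)
    side_amp_all = np.outer(X[:, side_j], gains[:, side_j])

    for i in range(len(trials)):
        # event kernels
        for ev_name, k in config.kernels.items():
            t0 = ev_times[ev_name][i] + k.onset_s
            add_box(t0, t0 + k.duration_s, k.amplitude_hz)
        # non-choice tuning during the cue-evaluation period
        add_box(cue[i], cue[i] + CUE_PERIOD_S, contrib_all[i] - side_amp_all[i])
        # chosen-side tuning: region 2's whole coding epoch (onset and
        # offset) is shifted by the lag relative to region 1
        lag = config.region_lag if correct[i] else lag_incorrect
        end = nosepoke[i] + 0.5
        on1 = cue[i] + config.tuning_onset
        box1 = np.zeros(n_units)
        box1[:n_per] = side_amp_all[i, :n_per]
        add_box(on1, end, box1)
        box2 = np.zeros(n_units)
        box2[n_per:] = side_amp_all[i, n_per:]
        add_box(on1 + lag, end + lag, box2)

    np.clip(rate, 0.0, None, out=rate)
    # inhomogeneous Poisson by thinning: homogeneous candidates at each
    # unit's max rate, accepted with probability rate(t)/max
    rmax = rate.max(axis=1)
    n_cand = rng.poisson(rmax * duration)
    unit_col = np.repeat(np.arange(n_units), n_cand)
    times = rng.random(unit_col.size) * duration
    bins = np.minimum((times / dt).astype(np.int64), n_bins - 1)
    accept = rng.random(unit_col.size) * rmax[unit_col] <= rate[unit_col, bins]
    unit_col, times = unit_col[accept], times[accept]
    del rate
    order = np.lexsort((times, unit_col))
    unit_col, times = unit_col[order], times[order]
    # enforce strictly increasing spike times within unit
    for _ in range(3):
        same = np.flatnonzero((np.diff(times) <= 0) & (np.diff(unit_col) == 0))
        if same.size == 0:
            break
        times[same + 1] = times[same] + 1e-9

    spikes = pd.DataFrame({"unit_id": unit_col, "spike_time": times})
    units = pd.DataFrame({"unit_id": unit_ids, "region": regions})
    return spikes, units, events, tuned_ids


def true_preference(config: SimConfig) -> float:
    """Ground-truth point of subjective equality, -b0/b1 (drops)."""
    if config.probit_slope == 0:
        raise ValueError("preference undefined for zero probit slope")
    return -config.probit_intercept / config.probit_slope


def is_correct_choice(trials: pd.DataFrame) -> np.ndarray:
    """True where the chosen offer was the (strictly) larger one.

    Equal-size trials are neither correct nor incorrect; they return False
    here and are excluded from accuracy denominators by the analysis side.
    """
    bc = trials["blackcurrant_drops"].to_numpy()
    lem = trials["lemon_drops"].to_numpy()
    chose_bc = trials["chosen_flavor"].to_numpy() == "blackcurrant"
    return np.where(chose_bc, bc > lem, lem > bc)


def gen_session(config: SimConfig, session_id: str = "s0",
                rat_id: str = "rat0") -> Session:
    """Generate one complete session (trials, events, spikes, units, truth)."""
    config.validate()
    ss = np.random.SeedSequence(config.rng_seed)
    r_trials, r_choices, r_spikes = (_rng(s) for s in ss.spawn(3))
    trials = gen_trials(config, r_trials)
    trials = gen_choices(trials, config, r_choices)
    spikes, units, events, tuned_ids = gen_spikes(trials, config, r_spikes)
    trials.insert(1, "session_id", session_id)
    trials.insert(2, "rat_id", rat_id)
    events.insert(1, "session_id", session_id)
    units.insert(1, "session_id", session_id)
    delta = trials["blackcurrant_drops"] - trials["lemon_drops"]
    p = norm.cdf(config.probit_intercept + config.probit_slope * delta)
    truth = GroundTruth(
        true_preference=true_preference(config),
        true_lag=config.region_lag,
        tuned_unit_ids=tuned_ids,
        p_choose_blackcurrant=np.asarray(p),
    )
    return Session(session_id, rat_id, trials, events, spikes, units,
                   copy.deepcopy(config), truth)


def gen_cohort(config: SimConfig, n_sessions: int, n_rats: int,
               rat_intercept_sd: float = 0.3) -> list[Session]:
    """Generate a cohort of sessions with per-rat persistent preferences.

    Rats are assigned round-robin across sessions.  Each rat draws one
    probit intercept (preference) that persists across all of its sessions;
    child seeds derive deterministically from the master seed, so the same
    master seed reproduces the cohort exactly.
    """
    if n_sessions <= 0 or n_rats <= 0:
        raise ValueError("n_sessions and n_rats must be positive")
    ss = np.random.SeedSequence(config.rng_seed)
    rat_ss, *session_ss = ss.spawn(n_sessions + 1)
    rat_rng = _rng(rat_ss)
    rat_b0 = config.probit_intercept + rat_rng.normal(0, rat_intercept_sd, n_rats)
    sessions = []
    for i in range(n_sessions):
        rat = i % n_rats
        seed = int(session_ss[i].generate_state(1)[0] % (2**31))
        cfg = replace(copy.deepcopy(config), probit_intercept=float(rat_b0[rat]),
                      rng_seed=seed)
        sessions.append(gen_session(cfg, session_id=f"s{i}", rat_id=f"rat{rat}"))
    return sessions
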