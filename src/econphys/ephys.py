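"""Spike-train preprocessing and single-unit statistics.

Spike counts are binned in 50-ms windows stepped at 25 ms and converted to
a z-scored firing rate over the whole session per unit.  Rates are aligned
to task events and the mean rate in the 500 ms before cue presentation is
subtracted per trial.  Units are classified as task-modulated with a
Wilcoxon rank-sum test of ten 500-ms trial epochs against the pre-cue
baseline (Benjamini-Hochberg FDR within unit, corrected threshold
P < 0.001), and per-variable tuning is assessed with single-variable
ordinary-least-squares regressions of the trial response on each of ten
predefined task variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import behavior

BIN_WIDTH_S = 0.050
BIN_STEP_S = 0.025
BASELINE_WINDOW_S = (-0.5, 0.0)   # relative to cue onset
N_EPOCHS = 10
EPOCH_LEN_S = 0.5
ALPHA = 0.001


@dataclass
class BinnedRates:
    """Session-wide per-unit z-scored firing rates on a uniform bin grid."""

    z: np.ndarray                # (units, bins)
    unit_ids: np.ndarray
    bin_starts: np.ndarray       # s, left edges; step BIN_STEP_S
    bin_width: float
    bin_step: float
    zero_variance: np.ndarray    # (units,) bool flag


@dataclass
class AlignedTensor:
    """Baseline-subtracted z-rates around a named event, per trial.

    ``values`` holds the baseline-subtracted z-scored rates; ``baseline``
    the per-unit per-trial mean z-rate over the 500 ms before cue onset
    (so raw aligned rates are ``values + baseline[:, :, None]``).
    """

    values: np.ndarray           # (units, trials, bins)
    baseline: np.ndarray         # (units, trials)
    times: np.ndarray            # s relative to the alignment event
    event: str
    unit_ids: np.ndarray
    trial_ids: np.ndarray
    bin_width: float = BIN_WIDTH_S
    bin_step: float = BIN_STEP_S
    dropped_trials: list = field(default_factory=list)

    @property
    def raw(self) -> np.ndarray:
        """Aligned z-rates with the per-trial baseline added back."""
        return self.values + self.baseline[:, :, None]


def bin_and_zscore(spikes: pd.DataFrame, session_duration: float,
                   unit_ids=None, bin_width: float = BIN_WIDTH_S,
                   bin_step: float = BIN_STEP_S) -> BinnedRates:
    """Bin spikes in overlapping windows and z-score each unit.

    Windows are ``[t, t + bin_width)`` with left edges on a ``bin_step``
    grid from 0.  Z-scoring uses each unit's mean/SD over all session bins;
    zero-variance units yield an all-zero series with a flag.  Unsorted
    spike times are sorted with a warning; negative times are an error.
    """
    t = spikes["spike_time"].to_numpy(dtype=float)
    u = spikes["unit_id"].to_numpy()
    if t.size and t.min() < 0:
        raise ValueError("negative spike times")
    if unit_ids is None:
        unit_ids = np.unique(u)
    unit_ids = np.asarray(unit_ids)
    n_bins = int(np.floor((session_duration - bin_width) / bin_step)) + 1
    if n_bins < 1:
        raise ValueError("session too short for a single bin")
    starts = np.arange(n_bins) * bin_step
    z = np.empty((len(unit_ids), n_bins))
    zero_var = np.zeros(len(unit_ids), dtype=bool)
    for i, uid in enumerate(unit_ids):
        ts = t[u == uid]
        if ts.size and np.any(np.diff(ts) < 0):
            warnings.warn(f"unit {uid}: spike times unsorted; sorting")
            ts = np.sort(ts)
        counts = (np.searchsorted(ts, starts + bin_width, side="left")
                  - np.searchsorted(ts, starts, side="left"))
        rate = counts / bin_width
        mu, sd = rate.mean(), rate.std()
        if sd == 0:
            zero_var[i] = True
            z[i] = 0.0
        else:
            z[i] = (rate - mu) / sd
    return BinnedRates(z=z, unit_ids=unit_ids, bin_starts=starts,
                       bin_width=bin_width, bin_step=bin_step,
                       zero_variance=zero_var)


def _bin_index(time_s: float, step: float) -> int:
    return int(round(time_s / step))


def align_and_baseline(binned: BinnedRates, events: pd.DataFrame,
                       event: str = "cue_onset",
                       window: tuple[float, float] = (-0.5, 5.0),
                       ) -> AlignedTensor:
    """Slice z-rates around an event and subtract the pre-cue baseline.

    For every trial the mean z-rate over the 500 ms before that trial's cue
    onset is subtracted from every bin (per unit).  Trials whose window
    falls outside the session are dropped with a reason.
    """
    if event not in events.columns:
        raise ValueError(f"unknown event column {event!r}")
    step = binned.bin_step
    n_rel = int(round((window[1] - window[0]) / step))
    rel_times = window[0] + np.arange(n_rel) * step
    n_base = int(round((BASELINE_WINDOW_S[1] - BASELINE_WINDOW_S[0]) / step)) - 1
    kept, slabs, bases, dropped = [], [], [], []
    cue = events["cue_onset"].to_numpy(dtype=float)
    ev = events[event].to_numpy(dtype=float)
    tids = events["trial_id"].to_numpy()
    n_bins_total = binned.z.shape[1]
    for k in range(len(events)):
        i0 = _bin_index(ev[k] + window[0], step)
        jc = _bin_index(cue[k], step)
        jb0 = jc - n_base - 1     # first baseline bin fully inside [-0.5, 0)
        if i0 < 0 or i0 + n_rel > n_bins_total or jb0 < 0:
            dropped.append((tids[k], "window outside session"))
            continue
        kept.append(k)
        slabs.append(binned.z[:, i0:i0 + n_rel])
        bases.append(binned.z[:, jb0:jc - 1].mean(axis=1))
    if not kept:
        raise ValueError("no trials with a complete alignment window")
    values = np.stack(slabs, axis=1)            # (units, trials, bins)
    baseline = np.stack(bases, axis=1)          # (units, trials)
    values = values - baseline[:, :, None]
    return AlignedTensor(values=values, baseline=baseline, times=rel_times,
                         event=event, unit_ids=binned.unit_ids,
                         trial_ids=tids[kept], bin_width=binned.bin_width,
                         bin_step=step, dropped_trials=dropped)


def ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact distribution for small tie-free samples, normal approximation
    with tie correction otherwise; all-identical pooled samples give p = 1.

    Inputs are rounded to 8 decimals first: binned firing-rate means are
    lattice-valued (spike counts), and float roundoff from averaging bins
    would otherwise split genuine ties and break the tie correction.
    """
    x = np.round(np.asarray(x, float), 8)
    y = np.round(np.asarray(y, float), 8)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    small = (x.size + y.size) <= 40
    method = "exact" if (small and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)


def _epoch_bin_mask(times: np.ndarray, lo: float, hi: float,
                    width: float) -> np.ndarray:
    # bins fully inside [lo, hi)
    return (times >= lo - 1e-9) & (times + width <= hi + 1e-9)


@dataclass
class UnitStats:
    """Per-unit modulation and tuning results."""

    unit_ids: np.ndarray
    epoch_p: np.ndarray            # (units, 10) raw rank-sum p
    epoch_p_adj: np.ndarray        # (units, 10) BH-adjusted within unit
    task_modulated: np.ndarray     # (units,) bool
    variables: tuple = ()
    slopes: np.ndarray | None = None       # (units, n_vars)
    slope_p: np.ndarray | None = None
    tuned: np.ndarray | None = None        # (units, n_vars) bool
    var_unavailable: tuple = ()            # variables excluded (zero variance)


def detect_task_modulation(tensor: AlignedTensor,
                           alpha: float = ALPHA) -> UnitStats:
    """Rank-sum tests of ten 500-ms trial epochs against pre-cue baseline.

    The tensor must be aligned to cue onset with a window covering
    [0, 5) s.  Per unit, each epoch's per-trial mean raw z-rate is compared
    with the per-trial baseline means; BH FDR is applied across the ten
    epochs within unit and the unit is flagged task-modulated if any
    adjusted p falls below ``alpha``.
    """
    if tensor.event != "cue_onset":
        raise ValueError("task-modulation screen requires cue-aligned tensor")
    raw = tensor.raw
    n_units = raw.shape[0]
    epoch_p = np.ones((n_units, N_EPOCHS))
    for e in range(N_EPOCHS):
        lo, hi = e * EPOCH_LEN_S, (e + 1) * EPOCH_LEN_S
        mask = _epoch_bin_mask(tensor.times, lo, hi, tensor.bin_width)
        if not mask.any():
            raise ValueError(f"alignment window does not cover epoch {e}")
        means = raw[:, :, mask].mean(axis=2)     # (units, trials)
        for i in range(n_units):
            epoch_p[i, e] = ranksum_p(means[i], tensor.baseline[i])
    adj = np.empty_like(epoch_p)
    for i in range(n_units):
        adj[i] = multipletests(epoch_p[i], method="fdr_bh")[1]
    flagged = (adj < alpha).any(axis=1)
    return UnitStats(unit_ids=tensor.unit_ids, epoch_p=epoch_p,
                     epoch_p_adj=adj, task_modulated=flagged)


def build_task_variables(trials: pd.DataFrame,
                         fit: behavior.PsychometricFit | None = None,
                         preference: float | None = None) -> pd.DataFrame:
    """Per-trial design matrix of the ten default task variables.

    Subjective value adds the preference score to lemon offers (the score
    is in blackcurrant-drop units); blackcurrant offers are unchanged.  If
    the preference is undefined the two subjective-value columns are
    omitted and listed in ``df.attrs['unavailable']``.
    """
    if preference is None and fit is not None:
        preference = (None if fit.preference_undefined
                      else fit.preference_score)
    from .synth import trial_variables
    if preference is None:
        x = trial_variables(trials, 0.0)
        x = x.drop(columns=["left_subjective_value", "right_subjective_value"])
        x.attrs["unavailable"] = ("left_subjective_value",
                                  "right_subjective_value")
    else:
        x = trial_variables(trials, float(preference))
        x.attrs["unavailable"] = ()
    x.index = trials.index
    return x


def tuning_regression(tensor: AlignedTensor, variables: pd.DataFrame,
                      response_window: tuple[float, float] = (0.0, 2.0),
                      alpha: float = ALPHA,
                      stats_in: UnitStats | None = None) -> UnitStats:
    """Single-variable OLS tuning regressions per unit.

    The trial response is the mean baseline-subtracted z-rate over the
    response window (default the 2-s cue-evaluation period).  Each variable
    is regressed separately; a unit is flagged tuned to a variable when the
    slope's two-sided t-test p falls below ``alpha``.  Zero-variance
    predictors are flagged unavailable and excluded.
    """
    mask = _epoch_bin_mask(tensor.times, *response_window, tensor.bin_width)
    if not mask.any():
        raise ValueError("response window contains no complete bins")
    resp = tensor.values[:, :, mask].mean(axis=2)   # (units, trials)
    if len(variables) != resp.shape[1]:
        raise ValueError("variables and tensor disagree on trial count")
    var_names = tuple(variables.columns)
    n_units = resp.shape[0]
    slopes = np.full((n_units, len(var_names)), np.nan)
    pvals = np.full((n_units, len(var_names)), np.nan)
    unavailable = []
    for j, v in enumerate(var_names):
        x = variables[v].to_numpy(dtype=float)
        if np.std(x) == 0:
            unavailable.append(v)
            continue
        for i in range(n_units):
            y = resp[i]
            if np.std(y) == 0:
                slopes[i, j], pvals[i, j] = 0.0, 1.0
                continue
            r = stats.linregress(x, y)
            slopes[i, j], pvals[i, j] = r.slope, r.pvalue
    tuned = np.where(np.isnan(pvals), False, pvals < alpha)
    out = stats_in if stats_in is not None else UnitStats(
        unit_ids=tensor.unit_ids,
        epoch_p=np.ones((n_units, N_EPOCHS)),
        epoch_p_adj=np.ones((n_units, N_EPOCHS)),
        task_modulated=np.zeros(n_units, dtype=bool))
    out.variables = var_names
    out.slopes = slopes
    out.slope_p = pvals
    out.tuned = tuned
    out.var_unavailable = tuple(unavailable)
    return out


def modulation_proportions(stats_list: list[UnitStats],
                           regions: list[str]) -> pd.DataFrame:
    """Fraction of units flagged per variable, by region.

    One UnitStats per region (tuning part populated).  Also reports the
    task-modulated fraction under the pseudo-variable ``task_modulated``.
    """
    if len(stats_list) != len(regions):
        raise ValueError("one UnitStats per region required")
    rows = {}
    for st, region in zip(stats_list, regions):
        n = len(st.unit_ids)
        if n == 0:
            raise ValueError(f"region {region!r} has no units")
        row = {"task_modulated": float(st.task_modulated.mean())}
        if st.tuned is not None:
            for j, v in enumerate(st.variables):
                if v in st.var_unavailable:
                    continue
                row[v] = float(st.tuned[:, j].mean())
        rows[region] = row
    return pd.DataFrame(rows).T
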