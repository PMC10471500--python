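"""Inter-region lag analysis of predicted choice parameters.

Single-trial choice-parameter series from two simultaneously recorded
regions are smoothed with a 50-ms Gaussian filter, cross-correlated in the
3 s surrounding the choice nosepoke (normalized Pearson correlation at
each lag, search bounded at +/-1 s), and the per-class correlograms are
averaged across trials and decoding repeats before peak-picking.  The lag
sign convention: the reported lag is the shift applied to region 1 that
best aligns it with region 2, so region 1 leading yields a NEGATIVE lag.
Correct (chose larger offer) and incorrect trials are analyzed separately
and compared across sessions with a two-sided paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d

BIN_STEP_S = 0.025
SMOOTH_SIGMA_S = 0.050      # analysis smoothing; 0.250 for visualization
MAX_LAG_S = 1.0
XCORR_WINDOW_S = 3.0        # centered on the choice nosepoke
THRESHOLD = 0.33


def smooth_series(series: np.ndarray, sigma: float,
                  dt: float = BIN_STEP_S, axis: int = -1) -> np.ndarray:
    """Gaussian smoothing (SD ``sigma`` seconds, reflective boundary).

    ``sigma = 0`` returns the input unchanged.  The time step must be
    uniform; pass it via ``dt``.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    series = np.asarray(series, dtype=float)
    if sigma == 0:
        return series.copy()
    return gaussian_filter1d(series, sigma / dt, axis=axis, mode="reflect")


def check_uniform(times: np.ndarray, dt: float | None = None) -> float:
    """Validate a uniform time axis; returns the step."""
    times = np.asarray(times, dtype=float)
    steps = np.diff(times)
    if steps.size == 0:
        raise ValueError("time axis too short")
    if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
        raise ValueError("non-uniform time axis")
    if dt is not None and not np.isclose(steps[0], dt, atol=1e-9):
        raise ValueError("time axis step does not match dt")
    return float(steps[0])


def _corr_at_lags(s1: np.ndarray, s2: np.ndarray, max_shift: int,
                  min_overlap: int = 10) -> np.ndarray:
    """Pearson correlation of s1[i+k] with s2[i] for k in [-K, K].

    ``s1``/``s2`` are (..., n) stacks of series; returns (..., 2K+1) with
    NaN where a window has zero variance or too little overlap.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError("series shapes differ")
    n = s1.shape[-1]
    out = np.full(s1.shape[:-1] + (2 * max_shift + 1,), np.nan)
    for j, kk in enumerate(range(-max_shift, max_shift + 1)):
        if kk >= 0:
            a = s1[..., kk:]
            b = s2[..., :n - kk] if kk else s2
        else:
            a = s1[..., :n + kk]
            b = s2[..., -kk:]
        if a.shape[-1] < min_overlap:
            continue
        am = a - a.mean(axis=-1, keepdims=True)
        bm = b - b.mean(axis=-1, keepdims=True)
        denom = np.sqrt((am * am).sum(axis=-1) * (bm * bm).sum(axis=-1))
        with np.errstate(invalid="ignore", divide="ignore"):
            c = (am * bm).sum(axis=-1) / denom
        out[..., j] = np.where(denom > 0, c, np.nan)
    return out


def _peak_lag(corr: np.ndarray, lags: np.ndarray) -> float:
    """Lag at the correlogram maximum; ties break toward the smallest |lag|."""
    valid = np.isfinite(corr)
    if not valid.any():
        return float("nan")
    m = np.nanmax(corr)
    cand = np.flatnonzero(valid & (corr >= m - 1e-12))
    best = cand[np.lexsort((lags[cand], np.abs(lags[cand])))[0]]
    return float(lags[best])


def xcorr_peak_lag(series1: np.ndarray, series2: np.ndarray,
                   dt: float = BIN_STEP_S, max_lag: float = MAX_LAG_S,
                   ) -> tuple[float, np.ndarray, np.ndarray]:
    """Peak of the normalized cross-correlogram of two single-trial series.

    Returns (lag_s, lags_s, correlogram).  The lag is the shift applied to
    ``series1`` that maximizes its Pearson correlation with ``series2``
    (series1 leading => negative lag); NaN if either window has zero
    variance.
    """
    K = int(round(max_lag / dt))
    lags = np.arange(-K, K + 1) * dt
    corr = _corr_at_lags(np.atleast_1d(series1), np.atleast_1d(series2), K)
    return _peak_lag(corr, lags), lags, corr


@dataclass
class LagResult:
    """Per-session peak cross-correlation lags by trial class."""

    session_id: str
    lag_correct: float             # s; negative <=> region 1 leads
    lag_incorrect: float           # NaN when the class has no usable trials
    n_correct: int
    n_incorrect: int
    lags: np.ndarray
    correlogram_correct: np.ndarray
    correlogram_incorrect: np.ndarray


def session_lag(cp1: np.ndarray, cp2: np.ndarray, correct: np.ndarray,
                eligible: np.ndarray | None = None,
                session_id: str = "", dt: float = BIN_STEP_S,
                sigma: float = SMOOTH_SIGMA_S, max_lag: float = MAX_LAG_S,
                peak_mode: str = "average-then-peak") -> LagResult:
    """Class-wise inter-region lag for one session.

    ``cp1``/``cp2`` are choice-parameter arrays (repeats, trials, bins)
    covering the 3-s window around the choice nosepoke on a common 25-ms
    grid.  Per trial and repeat the smoothed series are cross-correlated;
    correlograms are averaged across trials within class and across the
    decoding repeats, and the class lag is the peak of the class-average
    correlogram.  ``peak_mode='peak-then-average'`` instead averages
    per-trial peak lags.  ``eligible`` excludes trials belonging to
    neither class (equal-offer trials, which are neither correct nor
    incorrect).
    """
    if cp1.shape != cp2.shape:
        raise ValueError("region series shapes differ")
    if peak_mode not in ("average-then-peak", "peak-then-average"):
        raise ValueError(f"unknown peak_mode {peak_mode!r}")
    correct = np.asarray(correct, dtype=bool)
    if correct.size != cp1.shape[1]:
        raise ValueError("correct mask length does not match trials")
    eligible = (np.ones_like(correct) if eligible is None
                else np.asarray(eligible, dtype=bool))
    K = int(round(max_lag / dt))
    lags = np.arange(-K, K + 1) * dt
    s1 = smooth_series(cp1, sigma, dt)
    s2 = smooth_series(cp2, sigma, dt)
    corr = _corr_at_lags(s1, s2, K)          # (repeats, trials, lags)

    def class_stats(mask: np.ndarray) -> tuple[float, np.ndarray, int]:
        if not mask.any():
            return float("nan"), np.full(lags.size, np.nan), 0
        sub = corr[:, mask, :].reshape(-1, lags.size)
        usable = np.isfinite(sub).any(axis=1)
        if not usable.any():
            return float("nan"), np.full(lags.size, np.nan), 0
        avg = np.nanmean(sub[usable], axis=0)
        if peak_mode == "average-then-peak":
            lag = _peak_lag(avg, lags)
        else:
            per = [_peak_lag(row, lags) for row in sub[usable]]
            per = [v for v in per if np.isfinite(v)]
            lag = float(np.mean(per)) if per else float("nan")
        return lag, avg, int(mask.sum())

    lag_c, cg_c, n_c = class_stats(correct & eligible)
    lag_i, cg_i, n_i = class_stats(~correct & eligible)
    return LagResult(session_id=session_id, lag_correct=lag_c,
                     lag_incorrect=lag_i, n_correct=n_c, n_incorrect=n_i,
                     lags=lags, correlogram_correct=cg_c,
                     correlogram_incorrect=cg_i)


@dataclass
class LagComparison:
    mean_correct: float
    sem_correct: float
    mean_incorrect: float
    sem_incorrect: float
    t_stat: float
    df: int
    p_value: float
    n_sessions: int


def compare_lags(results: list[LagResult]) -> LagComparison:
    """Two-sided paired t-test of correct vs incorrect session lags.

    Sessions missing either class lag are dropped; all-zero differences
    give t = 0, p = 1 by convention.
    """
    c = np.array([r.lag_correct for r in results])
    i = np.array([r.lag_incorrect for r in results])
    ok = np.isfinite(c) & np.isfinite(i)
    c, i = c[ok], i[ok]
    n = c.size
    if n < 2:
        raise ValueError("need at least 2 sessions with both class lags")
    diff = c - i
    if np.all(diff == 0) or np.std(diff, ddof=1) == 0:
        t, p = (0.0, 1.0) if np.all(diff == 0) else (np.inf, 0.0)
    else:
        res = stats.ttest_rel(c, i)
        t, p = float(res.statistic), float(res.pvalue)
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(x.size))
    return LagComparison(mean_correct=float(c.mean()), sem_correct=sem(c),
                         mean_incorrect=float(i.mean()), sem_incorrect=sem(i),
                         t_stat=t, df=n - 1, p_value=p, n_sessions=n)


def threshold_latency(trace: np.ndarray, times: np.ndarray,
                      threshold: float = THRESHOLD,
                      normalize: bool = True) -> float:
    """First upward crossing of a threshold on a max-normalized trace.

    The trace is divided by its maximum (so values lie in [0, 1] for
    non-negative traces) and the first crossing of ``threshold`` from
    below is linearly interpolated between bins.  Returns NaN when the
    trace never crosses or its maximum is not positive.
    """
    trace = np.asarray(trace, dtype=float)
    times = np.asarray(times, dtype=float)
    if trace.shape != times.shape:
        raise ValueError("trace and times differ in length")
    y = trace.copy()
    if normalize:
        m = np.nanmax(y)
        if not np.isfinite(m) or m <= 0:
            return float("nan")
        y = y / m
    if y[0] >= threshold:
        return float(times[0])
    above = y >= threshold
    idx = np.flatnonzero(above & ~np.roll(above, 1))
    idx = idx[idx > 0]
    if idx.size == 0:
        return float("nan")
    i = idx[0]
    frac = (threshold - y[i - 1]) / (y[i] - y[i - 1])
    return float(times[i - 1] + frac * (times[i] - times[i - 1]))
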