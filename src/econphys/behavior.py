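"""Behavioral psychophysics: filtering, probit fits, preference, latency.

Choice behavior is summarized by a probit psychometric model

    P(choose blackcurrant) = Phi(b0 + b1 * delta),

where delta = blackcurrant drops - lemon drops offered on the trial.  The
preference score (point of subjective equality) is the delta at which the
animal is indifferent, -b0/b1; negative values indicate a blackcurrant
preference.  Accuracy is the fraction of unequal-offer trials on which the
larger total volume was chosen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.stats import norm

from .synth import COLLECTION_LIMIT_S, RESPONSE_LIMIT_S, is_correct_choice

REQUIRED_TRIAL_COLUMNS = (
    "blackcurrant_drops", "lemon_drops", "chosen_flavor",
    "response_latency", "collection_latency",
)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class EmptyDenominatorError(ValueError):
    """No trials eligible for the requested statistic."""


@dataclass
class PsychometricFit:
    """Probit coefficients and derived behavioral summaries."""

    beta0: float
    beta1: float
    n_trials_used: int
    accuracy: float
    preference_undefined: bool = False
    separation_fallback: bool = False

    @property
    def preference_score(self) -> float:
        """Point of subjective equality, -b0/b1 (drops)."""
        if self.preference_undefined:
            raise ValueError("preference undefined: psychometric slope ~ 0")
        return -self.beta0 / self.beta1

    def predict(self, delta: np.ndarray) -> np.ndarray:
        """Fitted P(choose blackcurrant) at the given drop differences."""
        return norm.cdf(self.beta0 + self.beta1 * np.asarray(delta, float))


def _check_columns(trials: pd.DataFrame, cols=REQUIRED_TRIAL_COLUMNS) -> None:
    for c in cols:
        if c not in trials.columns:
            raise SchemaError(f"trial table is missing required column {c!r}")


def delta_drops(trials: pd.DataFrame) -> np.ndarray:
    """Value difference per trial: blackcurrant drops - lemon drops."""
    return (trials["blackcurrant_drops"].to_numpy(dtype=float)
            - trials["lemon_drops"].to_numpy(dtype=float))


def filter_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Flag trials violating the response/collection latency filters.

    Trials with response latency > 12 s or reward-collection latency > 5 s
    are flagged excluded (missing collection latency counts as a timeout).
    Rows are never dropped or altered; order is preserved and the flags are
    added as ``excluded`` / ``exclusion_reason`` columns.
    """
    _check_columns(trials, ("response_latency", "collection_latency"))
    out = trials.copy()
    resp = out["response_latency"].to_numpy(dtype=float)
    coll = out["collection_latency"].to_numpy(dtype=float)
    slow_resp = resp > RESPONSE_LIMIT_S
    slow_coll = np.isnan(coll) | (coll > COLLECTION_LIMIT_S)
    reason = np.full(len(out), "", dtype=object)
    reason[slow_coll] = "collection>5s"
    reason[slow_resp] = "response>12s"  # response filter reported first
    out["excluded"] = slow_resp | slow_coll
    out["exclusion_reason"] = reason
    return out


def exclusion_counts(trials: pd.DataFrame) -> dict:
    """Counts of excluded trials by reason (after filter_trials)."""
    if "exclusion_reason" not in trials.columns:
        trials = filter_trials(trials)
    vc = trials.loc[trials["excluded"], "exclusion_reason"].value_counts()
    return {str(k): int(v) for k, v in vc.items()}


def retained(trials: pd.DataFrame) -> pd.DataFrame:
    """Rows passing the latency filters (pure selection, rows unaltered)."""
    flagged = filter_trials(trials)
    return flagged.loc[~flagged["excluded"]]


def choice_accuracy(trials: pd.DataFrame) -> float:
    """Fraction of unequal-offer trials where the larger reward was chosen.

    Equal-offer (delta = 0) trials are excluded from the denominator.
    """
    _check_columns(trials)
    unequal = delta_drops(trials) != 0
    if not unequal.any():
        raise EmptyDenominatorError("no trials with unequal offers")
    return float(is_correct_choice(trials)[unequal].mean())


def _probit_loglik(params: np.ndarray, delta: np.ndarray,
                   y: np.ndarray) -> float:
    eta = params[0] + params[1] * delta
    logp = norm.logcdf(eta)
    logq = norm.logcdf(-eta)
    return float(np.sum(y * logp + (1 - y) * logq))


def fit_psychometric(trials: pd.DataFrame, ridge: float = 1e-4) -> PsychometricFit:
    """Maximum-likelihood probit fit of choice on the drop difference.

    Fits indicator(chose blackcurrant) ~ Phi(b0 + b1*delta) by ML.  Under
    complete separation the ML estimate diverges; a small ridge penalty
    (``ridge`` * ||b||^2) is then applied and the fit flagged.  A slope
    indistinguishable from zero flags the preference score as undefined.
    """
    _check_columns(trials)
    if "excluded" in trials.columns:
        trials = trials.loc[~trials["excluded"]]
    delta = delta_drops(trials)
    y = (trials["chosen_flavor"].to_numpy() == "blackcurrant").astype(float)
    if len(np.unique(delta)) < 2:
        raise ValueError("need at least two distinct delta values to fit")

    fallback = False
    beta = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            X = sm.add_constant(delta)
            res = sm.Probit(y, X).fit(disp=0, maxiter=200)
            beta = np.asarray(res.params, dtype=float)
            converged = bool(res.mle_retvals.get("converged", True))
            if (not converged or not np.all(np.isfinite(beta))
                    or np.abs(beta).max() > 50):
                beta = None  # separation or non-convergence: penalized refit
        except Exception:
            beta = None
    if beta is None:
        fallback = True
        obj = lambda b: -_probit_loglik(b, delta, y) + ridge * float(b @ b)
        opt = optimize.minimize(obj, x0=np.zeros(2), method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 4000})
        beta = opt.x

    undefined = abs(beta[1]) < 1e-8
    try:
        acc = choice_accuracy(trials)
    except EmptyDenominatorError:
        acc = float("nan")
    return PsychometricFit(beta0=float(beta[0]), beta1=float(beta[1]),
                           n_trials_used=int(len(trials)), accuracy=acc,
                           preference_undefined=bool(undefined),
                           separation_fallback=fallback)


def preference_score(fit: PsychometricFit) -> float:
    """Delta at indifference, -b0/b1; negative = blackcurrant-preferring."""
    return fit.preference_score


def relative_latency(trials: pd.DataFrame) -> pd.Series:
    """Per-trial-type mean response latency, re-referenced to the fastest type.

    Trial type is the (blackcurrant drops, lemon drops) offer pair collapsed
    over presentation side.  The fastest type maps to exactly 0; types with
    no trials are omitted.
    """
    _check_columns(trials, ("blackcurrant_drops", "lemon_drops",
                            "response_latency"))
    if "excluded" in trials.columns:
        trials = trials.loc[~trials["excluded"]]
    if len(trials) == 0:
        return pd.Series(dtype=float)
    means = trials.groupby(["blackcurrant_drops", "lemon_drops"],
                           sort=True)["response_latency"].mean()
    return means - means.min()


def preference_stability(scores_a, scores_b) -> tuple[float, float]:
    """Pearson correlation of paired per-rat preference scores.

    Returns (r, two-sided p).  Raises on fewer than 3 pairs or zero
    variance in either vector.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("scores must be equal-length 1-D vectors")
    if a.size < 3:
        raise ValueError("need at least 3 paired scores")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("undefined correlation: zero variance")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


@dataclass
class CriterionResult:
    accuracy: float
    latency_rank_corr: float        # Spearman rho of latency vs |delta|
    latency_decreasing: bool
    passed: bool
    threshold: float


def session_criteria(trials: pd.DataFrame,
                     session_type: str = "choice") -> CriterionResult:
    """Apply the performance criteria for a session.

    Training sessions require accuracy strictly above 0.90 *and* response
    latency decreasing with the absolute reward-magnitude difference;
    choice sessions require accuracy strictly above 0.75.  Thresholds are
    strict inequalities.
    """
    if session_type not in ("training", "choice"):
        raise ValueError("session_type must be 'training' or 'choice'")
    acc = choice_accuracy(retained(trials) if "excluded" not in trials.columns
                          else trials.loc[~trials["excluded"]])
    use = trials.loc[~trials["excluded"]] if "excluded" in trials.columns else trials
    mag = np.abs(delta_drops(use))
    lat = use["response_latency"].to_numpy(dtype=float)
    if len(np.unique(mag)) < 2:
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(mag, lat).statistic)
    decreasing = bool(np.isfinite(rho) and rho < 0)
    threshold = 0.90 if session_type == "training" else 0.75
    passed = acc > threshold and (decreasing if session_type == "training"
                                  else True)
    return CriterionResult(accuracy=acc, latency_rank_corr=rho,
                           latency_decreasing=decreasing, passed=passed,
                           threshold=threshold)


@dataclass
class ConditionContrast:
    fits: dict = field(default_factory=dict)          # label -> PsychometricFit
    flagged: dict = field(default_factory=dict)       # label -> reason
    cross_condition_r: float | None = None
    cross_condition_p: float | None = None


def condition_contrast(trials: pd.DataFrame, condition_col: str = "condition",
                       min_trials: int = 20,
                       rat_col: str | None = None) -> ConditionContrast:
    """Fit the psychometric model independently per condition label.

    With ``rat_col`` given and at least 3 rats fit in both conditions, also
    reports the cross-condition Pearson correlation of per-rat preference
    scores (the condition-stability readout used for inhibition contrasts).
    Conditions with too few trials are flagged, never silently dropped.
    """
    if condition_col not in trials.columns:
        raise SchemaError(f"missing condition column {condition_col!r}")
    labels = sorted(trials[condition_col].dropna().unique())
    if len(labels) < 2:
        raise ValueError("need at least two condition labels")
    out = ConditionContrast()
    for lab in labels:
        sub = trials.loc[trials[condition_col] == lab]
        if len(sub) < min_trials:
            out.flagged[lab] = f"only {len(sub)} trials (< {min_trials})"
            continue
        try:
            out.fits[lab] = fit_psychometric(sub)
        except ValueError as e:
            out.flagged[lab] = str(e)
    if rat_col is not None and len(labels) == 2 and len(out.fits) == 2:
        per_rat: dict[str, list[float]] = {lab: [] for lab in labels}
        rats = sorted(trials[rat_col].dropna().unique())
        kept = []
        for rat in rats:
            scores = {}
            for lab in labels:
                sub = trials.loc[(trials[rat_col] == rat)
                                 & (trials[condition_col] == lab)]
                if len(sub) < min_trials:
                    break
                fit = fit_psychometric(sub)
                if fit.preference_undefined:
                    break
                scores[lab] = fit.preference_score
            if len(scores) == 2:
                kept.append(rat)
                for lab in labels:
                    per_rat[lab].append(scores[lab])
        if len(kept) >= 3:
            try:
                r, p = preference_stability(per_rat[labels[0]],
                                            per_rat[labels[1]])
                out.cross_condition_r, out.cross_condition_p = r, p
            except ValueError:
                pass
    return out
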