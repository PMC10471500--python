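"""Time-resolved linear decoding of chosen side from population activity.

A linear max-margin classifier (hinge loss, L2 penalty) is trained per
time bin on the aligned population z-rates with stratified fourfold
cross-validation; accuracy is the held-out fraction correct averaged over
folds and repeats.  The predicted choice parameter for a trial is the
signed perpendicular distance of its population vector from the decision
hyperplane, (w.x + b)/||w||, computed only from models of folds in which
the trial was held out — a single-trial proxy for decision confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

DEFAULT_C = 1.0
N_FOLDS = 4
N_REPEATS = 5


def match_units(populations: dict, seed: int) -> dict:
    """Subsample every population to the smallest population's size.

    Sampling is without replacement and deterministic under ``seed``.
    Populations already at the minimum size are returned unchanged (order
    preserved).
    """
    sizes = {k: len(v) for k, v in populations.items()}
    if any(s == 0 for s in sizes.values()):
        empty = [k for k, s in sizes.items() if s == 0]
        raise ValueError(f"empty population(s): {empty}")
    n_min = min(sizes.values())
    rng = np.random.default_rng(seed)
    out = {}
    for k in sorted(populations):
        v = np.asarray(populations[k])
        if len(v) == n_min:
            out[k] = v
        else:
            idx = np.sort(rng.choice(len(v), size=n_min, replace=False))
            out[k] = v[idx]
    return out


def build_pseudopopulation(session_tensors: list, session_labels: list,
                           n_pseudo_trials: int, seed: int,
                           ) -> tuple[np.ndarray, np.ndarray, list]:
    """Pool units across non-simultaneous sessions by label-matched resampling.

    For each pseudo-trial of a given chosen-side label, one real trial with
    that label is drawn (with replacement) from every session and the
    sessions' unit responses are concatenated.  Labels are balanced.
    Sessions lacking a label are excluded with a warning entry.

    Returns (features (units, pseudo_trials, bins), labels, excluded).
    """
    if n_pseudo_trials % 2:
        n_pseudo_trials += 1
    classes = (-1, 1)
    rng = np.random.default_rng(seed)
    usable, excluded = [], []
    for k, (tens, labs) in enumerate(zip(session_tensors, session_labels)):
        labs = np.asarray(labs)
        if all((labs == c).any() for c in classes):
            usable.append((tens, labs))
        else:
            excluded.append(k)
    if not usable:
        raise ValueError("no session has both labels")
    half = n_pseudo_trials // 2
    labels = np.array([classes[0]] * half + [classes[1]] * half)
    blocks = []
    for tens, labs in usable:
        picks = np.empty(n_pseudo_trials, dtype=int)
        for c in classes:
            pool = np.flatnonzero(labs == c)
            picks[labels == c] = rng.choice(pool, size=half, replace=True)
        blocks.append(tens[:, picks, :])
    return np.concatenate(blocks, axis=0), labels, excluded


def _standardize(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _fit_svm(Xtr: np.ndarray, ytr: np.ndarray, C: float) -> LinearSVC:
    # L2-regularized squared-hinge primal: the reliably convergent
    # liblinear formulation of the linear max-margin classifier
    clf = LinearSVC(C=C, loss="squared_hinge", dual=False,
                    max_iter=5000, tol=1e-4)
    clf.fit(Xtr, ytr)
    return clf


def _standardize_bins(train: np.ndarray, test: np.ndarray):
    """Per-bin per-feature standardization with training statistics.

    ``train``/``test`` are (bins, trials, features).
    """
    mu = train.mean(axis=1, keepdims=True)
    sd = train.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def fit_svm_bins(Xtr: np.ndarray, ytr: np.ndarray, C: float,
                 tol: float = 1e-7) -> tuple[np.ndarray, np.ndarray]:
    """Fit the linear max-margin classifier at every time bin jointly.

    Minimizes, independently per bin j, the same objective liblinear's
    primal squared-hinge solver minimizes (intercept regularized through
    feature augmentation):

        0.5 ||theta_j||^2 + C sum_i max(0, 1 - y_i theta_j . a_ij)^2

    with a = (x, 1).  All bins share one L-BFGS solve, which removes the
    per-bin solver-call overhead without changing the model.  Returns
    (W (bins, features), b (bins,)).
    """
    J, n, d = Xtr.shape
    y = np.asarray(ytr, dtype=float)
    A = np.concatenate([Xtr, np.ones((J, n, 1))], axis=2)
    Ay = A * y[None, :, None]

    def fg(theta_flat):
        theta = theta_flat.reshape(J, d + 1)
        margins = np.einsum("jnd,jd->jn", Ay, theta)
        slack = np.clip(1.0 - margins, 0.0, None)
        f = 0.5 * float(np.sum(theta * theta)) + C * float(np.sum(slack**2))
        grad = theta - 2.0 * C * np.einsum("jnd,jn->jd", Ay, slack)
        return f, grad.ravel()

    res = minimize(fg, np.zeros(J * (d + 1)), jac=True, method="L-BFGS-B",
                   options={"maxiter": 1000, "ftol": tol * 1e-3,
                            "gtol": tol})
    theta = res.x.reshape(J, d + 1)
    return theta[:, :d], theta[:, d]


def _decision_values(Xte: np.ndarray, W: np.ndarray,
                     b: np.ndarray) -> np.ndarray:
    """w.x + b per bin; (bins, trials)."""
    return np.einsum("jnd,jd->jn", Xte, W) + b[:, None]


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("need exactly two classes")
    if not np.array_equal(classes, [-1, 1]):
        raise ValueError("labels must be -1 (left) / +1 (right)")
    if min((labels == c).sum() for c in classes) < N_FOLDS:
        raise ValueError("too few trials per class for stratified folds")
    return labels


@dataclass
class DecodeResult:
    """Held-out classification accuracy per time bin."""

    accuracy: np.ndarray           # (bins,) mean over folds x repeats
    per_repeat: np.ndarray         # (repeats, bins)
    times: np.ndarray
    n_folds: int
    n_repeats: int
    n_units: int


def train_eval_timecourse(values: np.ndarray, labels: np.ndarray,
                          times: np.ndarray | None = None,
                          C: float = DEFAULT_C, n_repeats: int = N_REPEATS,
                          k: int = N_FOLDS, seed: int = 0,
                          shuffle_labels: bool = False) -> DecodeResult:
    """Fourfold cross-validated linear decoding at every time bin.

    ``values`` is (units, trials, bins); ``labels`` is chosen side coded
    -1/+1.  Features are standardized with training-fold statistics only.
    With ``shuffle_labels`` the labels are permuted independently per
    repeat — the chance-level control.
    """
    labels = _check_labels(labels)
    n_units, n_trials, n_bins = values.shape
    if times is None:
        times = np.arange(n_bins, dtype=float)
    acc = np.zeros((n_repeats, n_bins))
    rng = np.random.default_rng(seed)
    for rep in range(n_repeats):
        y = labels.copy()
        if shuffle_labels:
            y = rng.permutation(y)
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        folds = list(skf.split(np.zeros(n_trials), y))
        for tr_idx, te_idx in folds:
            Xtr, Xte = _standardize_bins(
                values[:, tr_idx, :].transpose(2, 1, 0),
                values[:, te_idx, :].transpose(2, 1, 0))
            W, b = fit_svm_bins(Xtr, y[tr_idx], C)
            pred = np.where(_decision_values(Xte, W, b) >= 0, 1, -1)
            acc[rep] += (pred == y[te_idx][None, :]).sum(axis=1)
        acc[rep] /= n_trials
    return DecodeResult(accuracy=acc.mean(axis=0), per_repeat=acc,
                        times=np.asarray(times), n_folds=k,
                        n_repeats=n_repeats, n_units=n_units)


def signed_distance(w: np.ndarray, b: float, x: np.ndarray) -> np.ndarray:
    """Perpendicular signed distance of point(s) x from hyperplane (w, b).

    Invariant under joint rescaling of (w, b); positive on the side w
    points to (the predicted-'right' side under the -1/+1 convention).
    """
    w = np.asarray(w, dtype=float)
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("degenerate model: zero weight vector")
    return (np.asarray(x, dtype=float) @ w + b) / nw


@dataclass
class ChoiceParameterSeries:
    """Signed hyperplane distances per (repeat, trial, time bin).

    Positive values mean the population state predicts a rightward choice.
    Within each repeat every trial is scored only by the model of the fold
    in which it was held out (fold-hygiene contract).
    """

    values: np.ndarray             # (repeats, trials, bins)
    times: np.ndarray
    labels: np.ndarray
    fold_of_trial: np.ndarray      # (repeats, trials) provenance

    @property
    def mean_over_repeats(self) -> np.ndarray:
        return self.values.mean(axis=0)


def choice_parameter(values: np.ndarray, labels: np.ndarray,
                     times: np.ndarray | None = None, C: float = DEFAULT_C,
                     n_repeats: int = N_REPEATS, k: int = N_FOLDS,
                     seed: int = 0) -> ChoiceParameterSeries:
    """Held-out signed hyperplane distance for every trial and time bin.

    Per repeat and time bin, a classifier is fitted on each training fold
    and its held-out trials are scored with (w.x + b)/||w||; across the k
    folds of a repeat every trial is scored exactly once.  The repeats x
    folds models are the "decoding repeats" averaged by the lag analysis.
    """
    labels = _check_labels(labels)
    n_units, n_trials, n_bins = values.shape
    if times is None:
        times = np.arange(n_bins, dtype=float)
    out = np.zeros((n_repeats, n_trials, n_bins))
    fold_of = np.full((n_repeats, n_trials), -1, dtype=int)
    rng = np.random.default_rng(seed)
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        for f, (tr_idx, te_idx) in enumerate(
                skf.split(np.zeros(n_trials), labels)):
            fold_of[rep, te_idx] = f
            Xtr, Xte = _standardize_bins(
                values[:, tr_idx, :].transpose(2, 1, 0),
                values[:, te_idx, :].transpose(2, 1, 0))
            W, b = fit_svm_bins(Xtr, labels[tr_idx], C)
            norms = np.linalg.norm(W, axis=1)
            if np.any(norms == 0):
                raise ValueError("degenerate model: zero weight vector")
            dist = _decision_values(Xte, W, b) / norms[:, None]
            out[rep, te_idx, :] = dist.T
    return ChoiceParameterSeries(values=out, times=np.asarray(times),
                                 labels=labels, fold_of_trial=fold_of)


@dataclass
class CrossConditionResult:
    accuracy_correct: np.ndarray       # (bins,) held-out CV on correct trials
    accuracy_incorrect: np.ndarray | None  # (bins,) correct-trained models
    times: np.ndarray
    n_correct: int
    n_incorrect: int
    no_incorrect_trials: bool


def cross_condition_eval(values: np.ndarray, labels: np.ndarray,
                         correct: np.ndarray,
                         times: np.ndarray | None = None,
                         C: float = DEFAULT_C, n_repeats: int = N_REPEATS,
                         k: int = N_FOLDS, seed: int = 0,
                         ) -> CrossConditionResult:
    """Train on correct trials; test on held-out correct and all incorrect.

    Both accuracies are scored against the side the animal actually chose,
    probing whether the population code tracks the chosen side regardless
    of choice correctness.  With no incorrect trials the incorrect-side
    accuracy is flagged missing rather than raising.
    """
    labels = _check_labels(labels)
    correct = np.asarray(correct, dtype=bool)
    n_units, n_trials, n_bins = values.shape
    if times is None:
        times = np.arange(n_bins, dtype=float)
    ci = np.flatnonzero(correct)
    ii = np.flatnonzero(~correct)
    yc = labels[ci]
    _check_labels(yc)
    acc_c = np.zeros((n_repeats, n_bins))
    acc_i = np.zeros((n_repeats, n_bins)) if ii.size else None
    rng = np.random.default_rng(seed)
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        n_models = 0
        for tr_idx, te_idx in skf.split(np.zeros(ci.size), yc):
            tr, te = ci[tr_idx], ci[te_idx]
            n_models += 1
            Xtr_raw = values[:, tr, :].transpose(2, 1, 0)
            Xtr, Xte = _standardize_bins(Xtr_raw,
                                         values[:, te, :].transpose(2, 1, 0))
            W, b = fit_svm_bins(Xtr, labels[tr], C)
            pred = np.where(_decision_values(Xte, W, b) >= 0, 1, -1)
            acc_c[rep] += (pred == labels[te][None, :]).sum(axis=1)
            if acc_i is not None:
                _, Xinc = _standardize_bins(
                    Xtr_raw, values[:, ii, :].transpose(2, 1, 0))
                predi = np.where(_decision_values(Xinc, W, b) >= 0, 1, -1)
                acc_i[rep] += (predi == labels[ii][None, :]).mean(axis=1)
        acc_c[rep] /= ci.size
        if acc_i is not None:
            acc_i[rep] /= n_models
    return CrossConditionResult(
        accuracy_correct=acc_c.mean(axis=0),
        accuracy_incorrect=None if acc_i is None else acc_i.mean(axis=0),
        times=np.asarray(times), n_correct=int(ci.size),
        n_incorrect=int(ii.size), no_incorrect_trials=ii.size == 0)
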