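# Methods

`econphys` analyzes two-alternative economic-choice behavior in rodents
together with simultaneous two-region extracellular recordings, and ships a
ground-truth simulator so that every analysis stage is validated by
parameter recovery rather than by eyeballing. This note documents the
models, the defaults and why they were chosen, the numerical conventions,
and what the synthetic validation does and does not establish.

## Task and behavioral model

Each trial offers two visual cues side by side: one predicts 0–3 drops of
blackcurrant-flavored water, the other 0–3 drops of lemon-flavored water,
with the all-zero pair excluded (15 offer combinations; the flavor-to-side
assignment is randomized per trial). After a mandatory 2-s cue period the
animal nosepokes to the side of the chosen cue and collects the reward.
Trials with response latency > 12 s or reward-collection latency > 5 s are
excluded before any analysis; exclusion is a pure row flag
(`behavior.filter_trials`) and never mutates retained rows.

Choice is modeled by a probit psychometric function of the drop
difference Δ = blackcurrant − lemon:

    P(choose blackcurrant) = Φ(β₀ + β₁ Δ)

The **preference score** (point of subjective equality) is −β₀/β₁, in
drops; negative values mean the animal prefers blackcurrant. Fitting is
maximum-likelihood probit (statsmodels). The regressor set is the single
predictor Δ plus an intercept: the preference score is defined purely on
Δ, and side/position covariates would not change it under per-trial side
randomization. Under complete separation the ML estimate diverges, so the
fit falls back to a ridge-penalized likelihood (λ = 1e-4, Nelder–Mead) and
sets `separation_fallback`. A slope below 1e-8 marks the preference score
undefined rather than returning ±∞.

**Accuracy** is the fraction of unequal-offer trials on which the larger
total volume was chosen; Δ = 0 trials are excluded from the denominator.
Session criteria use strict inequalities (> 0.90 training with a negative
latency-vs-|Δ| rank correlation, > 0.75 choice sessions). **Relative
latency** is computed per trial type — the offer pair collapsed over
presentation side — as the mean response latency minus the fastest type's
mean, so its minimum is exactly 0.

## Spike preprocessing

Spike counts are binned in 50-ms windows stepped at 25 ms (bins are
half-open `[t, t+0.05)` with left edges on the 25-ms grid) and converted to
a z-scored firing rate using each unit's mean and SD over **all bins of the
session**. Zero-variance units yield an all-zero trace plus a flag. Rates
are aligned to task events (cue onset, choice nosepoke, reward delivery)
by snapping the event to the nearest bin edge, and the mean z-rate in the
500 ms before that trial's cue onset is subtracted per trial and unit. The
tensor keeps the subtracted baselines so raw aligned rates remain
reconstructible.

**Task-modulated units.** Per unit, the per-trial mean rates in ten
consecutive 500-ms epochs spanning [0, 5) s from cue onset are each
compared with the per-trial baseline means by a two-sided Wilcoxon
rank-sum test (exact distribution for small tie-free samples, normal
approximation with tie correction otherwise; identical pooled samples give
p = 1 rather than NaN). Benjamini–Hochberg FDR is applied within unit
across the ten epochs, and the unit is flagged if any adjusted p < 0.001.

**Tuning.** For each unit, the trial response (mean baseline-subtracted
z-rate over a configurable window, default the 0–2 s cue-evaluation
period) is regressed separately on each of ten predefined task variables:
left offered size, right offered size, chosen side (±1), chosen flavor
(±1), chosen size, unchosen size, size sum, size difference (left−right),
and left/right **subjective value**. Subjective value adds the behavioral
preference score (blackcurrant-drop units) to lemon offers, leaving
blackcurrant offers unchanged. A unit is tuned to a variable when the OLS
slope's two-sided t-test p < 0.001; zero-variance predictors are flagged
unavailable and excluded from proportions.

## Decoding and the predicted choice parameter

Chosen side (left = −1 / right = +1) is decoded per time bin with a
fourfold stratified cross-validated linear max-margin classifier.
Features are standardized per bin using training-fold statistics only.
The solver minimizes the L2-regularized squared-hinge primal (the
liblinear formulation, C default 1.0, intercept regularized through
feature augmentation); all bins are solved jointly by one L-BFGS call
(`decoding.fit_svm_bins`), which is numerically identical to per-bin
liblinear solutions (verified to ~1e-4 in the tests) but removes per-bin
solver-call overhead. Accuracy is the held-out fraction correct averaged
over 4 folds × 5 repeats.

The **predicted choice parameter** of a trial at time t is the signed
perpendicular distance of its population vector from that bin's decision
hyperplane, (w·x + b)/‖w‖ — positive for predicted-right — computed only
by models of folds in which the trial was held out (fold hygiene is
asserted by bookkeeping). The 4 folds × 5 repeats give 20 fold-models per
session, the "decoding repeats" averaged by the lag analysis. The
parameter is invariant under joint rescaling of (w, b).

For population-size comparability across regions, `match_units`
subsamples every population without replacement to the smallest
population's size, deterministically under a seed. Units recorded in
different sessions can be pooled into a pseudo-population by label-matched
trial resampling (`build_pseudopopulation`), with labels balanced by
construction. Decoders are trained and tested at the same time bin;
temporal generalization is out of scope.

`cross_condition_eval` trains on correct trials (chose the larger offer)
only and scores both held-out correct trials and all incorrect trials
against the side actually chosen, probing whether the population encodes
the chosen side irrespective of choice correctness.

## Inter-region lag analysis

Single-trial choice parameters of the two regions, in the 3 s centered on
the choice nosepoke, are smoothed with a 50-ms Gaussian (reflective
boundary; 250 ms is for visualization only) and cross-correlated: at each
lag on the 25-ms grid, the Pearson correlation of the overlapping
segments (each mean-subtracted and unit-normalized per lag). The lag is
the shift applied to region 1 that maximizes alignment with region 2, so
**region 1 leading yields a negative lag**. In the generator, a positive
`region_lag` L delays region 2's chosen-side onset, so recovery
experiments expect a lag of −L.

Per-trial correlograms are averaged across trials within class (correct =
chose larger, incorrect = chose smaller; equal-offer trials belong to
neither) and across the 20 fold-model repeats; the class lag is the peak
of the class-average correlogram. Averaging correlograms before
peak-picking is the default because single-trial correlograms are too
noisy for stable per-trial peaks; `peak_mode="peak-then-average"` provides
the alternative. The lag search is bounded at ±1 s; ties at the peak break
toward the smallest |lag|. Session class lags are compared across sessions
by a two-sided paired t-test (all-zero differences give t = 0, p = 1).

**Threshold latency.** A rising timecourse (e.g. decoding accuracy above
chance) is divided by its own maximum and the first upward crossing of
0.33 is linearly interpolated between bins; traces that never cross are
flagged undefined. The 0.33 referent is applied to max-normalized traces
and is configurable.

## The synthetic generator

`synth.gen_session` produces a full session: offers, probit choices,
latencies, event times and two regions of inhomogeneous-Poisson units.
Defaults (units in parentheses):

| parameter | default | rationale |
|---|---|---|
| n_trials | 600 | the task's session cap |
| probit slope β₁ (1/drop) | 0.6 | gives ≈0.82 choose-larger accuracy over the 15-combination layout, matching observed rat behavior |
| probit intercept β₀ | 0.3 | mild blackcurrant preference (PSE −0.5 drops), the common direction |
| latency base / slope (s, s/drop) | 1.0 / 0.15 | seconds-scale responses, faster on easy trials |
| latency noise SD (s) | 0.25 | trial-to-trial jitter |
| p_violation | 0.02 | occasional filter-violating trials |
| ITI (s) | U(5, 10) | task timing |
| handling delay (s) | 0.5 | nosepoke → reward delivery (simulator convention) |
| baseline rate (Hz) | 5 | typical cortical/striatal single-unit rates |
| event kernels (Hz, s) | 3.0 for 0.5 | boxcar bumps at cue, nosepoke, reward |
| tuning gains (Hz) | side 3.0, sizes 1.0 | side coding comparable to event responses |
| chosen-side onset (s after cue) | 2.5 | shortly before the typical nosepoke (≈3 s), so the onset transition falls inside the 3-s lag window around the choice |
| region lag L (s) | 0.05 | region 1 leads by 50 ms |
| simulation step (s) | 0.005 | rate discretization for the Poisson draw |

Unit rates are `rectify(baseline + Σ event kernels + Σ gain·variable)`;
non-choice variables modulate rate during the 2-s cue period, chosen-side
coding from `cue + onset` (region 2: + L; optionally a different lag on
incorrect trials) until 0.5 s after the nosepoke. Spikes are drawn by
thinning a homogeneous process at each unit's maximum rate — exact for
piecewise-constant rates — and spike times are strictly increasing per
unit. Each stage consumes an independent child stream of the master seed
(`SeedSequence.spawn`), so identical config + seed reproduces every table
byte for byte. Cohorts draw one probit intercept per rat that persists
across that rat's sessions.

**What the generator does not emulate:** behavioral drift and satiety,
refractory periods and bursting, spike-sorting contamination, correlated
noise between units, non-stationary baselines, and any physiological
realism of the inhibition conditions (condition contrasts are emulated
purely by changing behavioral parameters). Passing recovery tests
therefore establishes the correctness and calibration of the analysis
code under the stated statistical model, not robustness to every
real-data pathology.

## Validation experiments and problem sizes

The recovery suite (`econphys.recovery`) runs at these sizes, chosen to
give stable statistics at desk scale:

- Preference recovery: 100 simulations × 2,000 trials, β₀ ∈ [−1, 1],
  β₁ ∈ [0.5, 3]; the median |PSE error| must be below 0.1 drops, and the
  probit fit must agree with a coarse-to-fine likelihood grid search to
  1e-3 on a 200-trial fixture.
- Null calibration: one session of 200 homogeneous-Poisson units × 100
  trials with no modulation at all; both screens' flag rates must stay
  within 3 binomial SEs of the 0.001 threshold.
- Decoder calibration: one 200-trial session; labels shuffled
  independently per repeat must stay inside the per-bin binomial 99% band
  of 0.5 at every bin, and strongly side-tuned units (6 Hz gain) must
  exceed 0.9 accuracy once side coding is on.
- Lag recovery: injected lags {−100, −50, −25, 0, +25, +50, +100} ms ×
  20 sessions each (24 units/region, 150 trials, 5 CV repeats); the median
  recovered lag must fall within one 25-ms bin of −L and the sign must be
  correct in ≥95% of sessions for |L| ≥ 50 ms.
- Paired-test power: 50 cohorts of 30 sessions with 70-ms class
  separation and 30-ms noise; p < 0.01 in ≥90% of cohorts.

## Known limitations

- The cross-correlogram peak is mildly attenuated toward zero for large
  true lags (≥ 100 ms) because the two regions share zero-lag,
  cue-locked signal components; recovered medians remain within one bin.
- Rank-sum epoch tests treat trials as exchangeable; slow within-session
  drift would inflate the false-flag rate beyond the null calibration.
- The per-bin decoder ignores temporal structure across bins by design.
- Pseudo-population resampling destroys cross-session noise correlations
  (none exist between non-simultaneous sessions anyway), so its accuracy
  estimates are optimistic relative to simultaneous populations.
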