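"""Psychometrics: filters, accuracy, probit fit vs grid oracle, latencies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from econphys import behavior, synth
from econphys.recovery import grid_search_probit


class TestFilterTrials:
    def test_hand_fixture_two_exclusions(self, hand_trials):
        flagged = behavior.filter_trials(hand_trials)
        assert int(flagged["excluded"].sum()) == 2
        assert len(flagged) == 10
        reasons = behavior.exclusion_counts(flagged)
        assert reasons == {"response>12s": 1, "collection>5s": 1}

    def test_response_over_12s_excluded(self, hand_trials):
        flagged = behavior.filter_trials(hand_trials)
        assert bool(flagged.loc[flagged["response_latency"] == 12.5,
                                "excluded"].iloc[0])

    def test_boundary_not_excluded(self):
        t = pd.DataFrame({"response_latency": [12.0, 11.9],
                          "collection_latency": [5.0, 4.9]})
        flagged = behavior.filter_trials(t)
        assert not flagged["excluded"].any()

    def test_empty_table(self):
        t = pd.DataFrame({"response_latency": [], "collection_latency": []})
        flagged = behavior.filter_trials(t)
        assert len(flagged) == 0 and not flagged["excluded"].any()

    def test_missing_collection_latency_excluded(self):
        t = pd.DataFrame({"response_latency": [1.0],
                          "collection_latency": [np.nan]})
        assert behavior.filter_trials(t)["excluded"].iloc[0]

    def test_missing_column_names_column(self):
        with pytest.raises(behavior.SchemaError, match="response_latency"):
            behavior.filter_trials(pd.DataFrame({"collection_latency": []}))

    def test_retained_rows_unaltered(self, hand_trials):
        kept = behavior.retained(hand_trials)
        cols = hand_trials.columns
        pd.testing.assert_frame_equal(
            kept[cols].reset_index(drop=True),
            hand_trials.loc[kept.index, cols].reset_index(drop=True))


class TestChoiceAccuracy:
    def test_hand_count(self, hand_trials):
        kept = behavior.retained(hand_trials)
        # 7 unequal-offer trials retained; 1 error (chose 0 over 1 drop)
        assert behavior.choice_accuracy(kept) == pytest.approx(6 / 7)

    def test_equal_offers_excluded_from_denominator(self):
        t = pd.DataFrame({
            "blackcurrant_drops": [2, 2, 3], "lemon_drops": [2, 2, 1],
            "chosen_flavor": ["lemon", "blackcurrant", "blackcurrant"],
            "response_latency": [1.0] * 3, "collection_latency": [1.0] * 3})
        assert behavior.choice_accuracy(t) == 1.0

    def test_all_equal_offers_raises(self):
        t = pd.DataFrame({
            "blackcurrant_drops": [2], "lemon_drops": [2],
            "chosen_flavor": ["lemon"], "response_latency": [1.0],
            "collection_latency": [1.0]})
        with pytest.raises(behavior.EmptyDenominatorError):
            behavior.choice_accuracy(t)

    def test_random_chooser_near_half(self):
        cfg = synth.SimConfig(n_trials=10_000, probit_intercept=0.0,
                              probit_slope=0.0, p_violation=0.0, rng_seed=20)
        trials = synth.gen_choices(synth.gen_trials(cfg), cfg)
        acc = behavior.choice_accuracy(trials)
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / 8000)


class TestFitPsychometric:
    def test_recovers_generating_coefficients(self):
        cfg = synth.SimConfig(n_trials=20_000, probit_intercept=1.0,
                              probit_slope=2.0, p_violation=0.0, rng_seed=21)
        trials = synth.gen_choices(synth.gen_trials(cfg), cfg)
        fit = behavior.fit_psychometric(trials)
        assert fit.beta0 == pytest.approx(1.0, rel=0.05)
        assert fit.beta1 == pytest.approx(2.0, rel=0.05)

    def test_matches_grid_search_oracle_small_fixture(self):
        cfg = synth.SimConfig(n_trials=50, probit_intercept=0.4,
                              probit_slope=0.7, p_violation=0.0, rng_seed=22)
        trials = synth.gen_choices(synth.gen_trials(cfg), cfg)
        fit = behavior.fit_psychometric(trials)
        delta = behavior.delta_drops(trials)
        chose = trials["chosen_flavor"] == "blackcurrant"
        b0, b1 = grid_search_probit(delta, chose)
        assert fit.beta0 == pytest.approx(b0, abs=1e-3)
        assert fit.beta1 == pytest.approx(b1, abs=1e-3)

    def test_separation_falls_back_with_flag(self):
        # deterministic chooser of the larger offer: complete separation
        t = pd.DataFrame({
            "blackcurrant_drops": [3, 3, 0, 0, 2, 1] * 5,
            "lemon_drops": [0, 1, 3, 2, 0, 3] * 5,
            "chosen_flavor": (["blackcurrant"] * 2 + ["lemon"] * 2
                              + ["blackcurrant"] + ["lemon"]) * 5,
            "response_latency": [1.0] * 30,
            "collection_latency": [1.0] * 30})
        fit = behavior.fit_psychometric(t)
        assert fit.separation_fallback
        assert np.isfinite(fit.beta0) and np.isfinite(fit.beta1)
        assert fit.beta1 > 0

    def test_single_delta_value_raises(self):
        t = pd.DataFrame({
            "blackcurrant_drops": [2] * 6, "lemon_drops": [1] * 6,
            "chosen_flavor": ["blackcurrant", "lemon"] * 3,
            "response_latency": [1.0] * 6, "collection_latency": [1.0] * 6})
        with pytest.raises(ValueError):
            behavior.fit_psychometric(t)


class TestPreferenceScore:
    def test_closed_form(self):
        fit = behavior.PsychometricFit(beta0=1.0, beta1=2.0,
                                       n_trials_used=0, accuracy=1.0)
        assert behavior.preference_score(fit) == pytest.approx(-0.5)

    def test_zero_intercept_gives_zero(self):
        fit = behavior.PsychometricFit(beta0=0.0, beta1=1.5,
                                       n_trials_used=0, accuracy=1.0)
        assert behavior.preference_score(fit) == 0.0

    def test_blackcurrant_preferrer_negative_score(self):
        cfg = synth.SimConfig(n_trials=5000, probit_intercept=0.8,
                              probit_slope=1.0, p_violation=0.0, rng_seed=23)
        trials = synth.gen_choices(synth.gen_trials(cfg), cfg)
        fit = behavior.fit_psychometric(trials)
        assert behavior.preference_score(fit) < 0

    def test_zero_slope_undefined(self):
        fit = behavior.PsychometricFit(beta0=1.0, beta1=0.0,
                                       n_trials_used=0, accuracy=0.5,
                                       preference_undefined=True)
        with pytest.raises(ValueError):
            behavior.preference_score(fit)


class TestRelativeLatency:
    def test_hand_subtraction(self):
        t = pd.DataFrame({
            "blackcurrant_drops": [1, 1, 2, 2, 3, 3],
            "lemon_drops": [0, 0, 1, 1, 0, 0],
            "response_latency": [0.8, 0.8, 0.5, 0.5, 1.1, 1.1],
            "collection_latency": [1.0] * 6,
            "chosen_flavor": ["blackcurrant"] * 6})
        rel = behavior.relative_latency(t)
        assert rel[(1, 0)] == pytest.approx(0.3)
        assert rel[(2, 1)] == pytest.approx(0.0)
        assert rel[(3, 0)] == pytest.approx(0.6)

    def test_minimum_is_exactly_zero(self, small_session):
        rel = behavior.relative_latency(
            behavior.retained(small_session.trials))
        assert rel.min() == 0.0

    def test_latency_increases_toward_difficult_trials(self):
        """Generator latency decreases in |delta|, so relative latency
        should rise as |delta| falls."""
        cfg = synth.SimConfig(n_trials=20_000, latency_noise_sd=0.05,
                              p_violation=0.0, rng_seed=24)
        trials = synth.gen_choices(synth.gen_trials(cfg), cfg)
        rel = behavior.relative_latency(trials)
        by_absdelta = rel.groupby(
            lambda k: abs(k[0] - k[1])).mean()
        vals = by_absdelta.sort_index().to_numpy()
        assert np.all(np.diff(vals) < 0)


class TestPreferenceStability:
    def test_identity_and_negation(self):
        a = [0.3, -0.2, 0.8, -1.0]
        r, _ = behavior.preference_stability(a, a)
        assert r == pytest.approx(1.0)
        r, _ = behavior.preference_stability(a, [-x for x in a])
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        a = rng.normal(size=12)
        b = 0.6 * a + rng.normal(size=12)
        r, p = behavior.preference_stability(a, b)
        expect = (np.sum((a - a.mean()) * (b - b.mean()))
                  / np.sqrt(np.sum((a - a.mean()) ** 2)
                            * np.sum((b - b.mean()) ** 2)))
        assert r == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            behavior.preference_stability([1, 1, 1], [0.1, 0.2, 0.3])


class TestSessionCriteria:
    def test_choice_session_thresholds_strict(self):
        def fake(acc_n, total=100):
            n_corr = acc_n
            rows = []
            for i in range(total):
                correct = i < n_corr
                rows.append({
                    "blackcurrant_drops": 2, "lemon_drops": 1 - (i % 2) * 2 + 1,
                    "chosen_flavor": "blackcurrant" if correct else "lemon",
                    "response_latency": 1.0, "collection_latency": 1.0})
            df = pd.DataFrame(rows)
            # ensure all offers unequal: lemon in {0, 2}? make simple: 2 vs 0
            df["lemon_drops"] = 0
            df.loc[~df.index.isin(range(n_corr)), "chosen_flavor"] = "lemon"
            return df
        assert behavior.session_criteria(fake(76), "choice").passed
        assert not behavior.session_criteria(fake(75), "choice").passed

    def test_training_requires_latency_decreasing(self):
        rows = []
        for i in range(200):
            d = [1, 2, 3][i % 3]
            rows.append({
                "blackcurrant_drops": d, "lemon_drops": 0,
                "chosen_flavor": "blackcurrant",
                "response_latency": 0.5 + 0.2 * d,  # increasing: must fail
                "collection_latency": 1.0})
        res = behavior.session_criteria(pd.DataFrame(rows), "training")
        assert res.accuracy == 1.0
        assert not res.passed


class TestConditionContrast:
    def test_flatter_curve_recovered_in_inhibited_condition(self):
        cfg_a = synth.SimConfig(n_trials=3000, probit_slope=1.5,
                                p_violation=0.0, rng_seed=25)
        cfg_b = synth.SimConfig(n_trials=3000, probit_slope=0.5,
                                p_violation=0.0, rng_seed=26)
        ta = synth.gen_choices(synth.gen_trials(cfg_a), cfg_a)
        tb = synth.gen_choices(synth.gen_trials(cfg_b), cfg_b)
        ta["condition"] = "uninhibited"
        tb["condition"] = "inhibited"
        both = pd.concat([ta, tb], ignore_index=True)
        cc = behavior.condition_contrast(both)
        assert cc.fits["inhibited"].beta1 < cc.fits["uninhibited"].beta1

    def test_rerandomized_preferences_decorrelate_across_conditions(self):
        """Cohort where per-rat preference is redrawn only in condition B:
        the cross-condition preference correlation collapses toward 0,
        while identical preferences give correlation near 1."""
        rng = np.random.default_rng(99)
        def cohort(reshuffle):
            frames = []
            b0s = rng.uniform(-1, 1, 8)
            for r, b0_a in enumerate(b0s):
                b0_b = rng.uniform(-1, 1) if reshuffle else b0_a
                for cond, b0 in (("a", b0_a), ("b", b0_b)):
                    cfg = synth.SimConfig(n_trials=800, probit_intercept=b0,
                                          probit_slope=1.2, p_violation=0.0,
                                          rng_seed=int(rng.integers(2**31)))
                    t = synth.gen_choices(synth.gen_trials(cfg), cfg)
                    t["condition"] = cond
                    t["rat_id"] = f"rat{r}"
                    frames.append(t)
            return pd.concat(frames, ignore_index=True)
        same = behavior.condition_contrast(cohort(False), rat_col="rat_id")
        resh = behavior.condition_contrast(cohort(True), rat_col="rat_id")
        assert same.cross_condition_r > 0.9
        assert abs(resh.cross_condition_r) < 0.6

    def test_small_condition_flagged_not_dropped(self):
        cfg = synth.SimConfig(n_trials=500, p_violation=0.0, rng_seed=27)
        t = synth.gen_choices(synth.gen_trials(cfg), cfg)
        t["condition"] = "a"
        t.loc[:3, "condition"] = "b"
        cc = behavior.condition_contrast(t)
        assert "b" in cc.flagged and "a" in cc.fits


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.1, 10.0), min_size=2, max_size=8))
def test_relative_latency_minimum_always_zero(latencies):
    """Property: the fastest trial type maps to exactly 0."""
    rows = []
    for i, lat in enumerate(latencies):
        rows.append({"blackcurrant_drops": i % 4, "lemon_drops": i // 4 + 1,
                     "response_latency": lat, "collection_latency": 1.0,
                     "chosen_flavor": "lemon"})
    rel = behavior.relative_latency(pd.DataFrame(rows))
    assert rel.min() == 0.0
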