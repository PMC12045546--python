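import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from reconpref import (
    backward_aic,
    bmi_compare,
    paired_compare,
    rank_utility_correlation,
    univariate_screen,
)


class TestSpearman:
    def test_perfect_inverse_monotone_is_minus_one(self):
        ranks = np.arange(1, 10)
        utilities = np.linspace(0.99, 0.5, 9)
        res = rank_utility_correlation(ranks, utilities)
        assert res.statistic == -1.0

    def test_statistic_matches_rank_then_pearson_oracle_with_ties(self):
        x = np.array([1.0, 2.0, 2.0, 4.0, 5.0, 6.0, 7.5, 7.5])
        y = np.array([3.0, 1.0, 4.0, 4.0, 6.0, 5.0, 8.0, 7.0])
        res = rank_utility_correlation(x, y)
        oracle = sps.pearsonr(sps.rankdata(x), sps.rankdata(y)).statistic
        assert res.statistic == pytest.approx(oracle, abs=1e-12)

    def test_null_correlation_small_under_independence(self, rng):
        hits = 0
        reps = 100
        for _ in range(reps):
            res = rank_utility_correlation(rng.normal(size=1000),
                                           rng.normal(size=1000))
            hits += abs(res.statistic) < 0.1
        assert hits / reps >= 0.95

    def test_constant_vector_reported_missing_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            res = rank_utility_correlation([1.0] * 5, [1, 2, 3, 4, 5])
        assert np.isnan(res.statistic) and np.isnan(res.p_value)
        assert res.degenerate

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            rank_utility_correlation([1, 2], [2, 1])


class TestWilcoxon:
    def test_identical_vectors_degenerate_p_one(self):
        res = paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p_value == 1.0 and res.n == 0

    def test_uniform_shift_strongly_significant(self, rng):
        x = rng.normal(size=20)
        res = paired_compare(x + 1.0, x)
        assert res.p_value < 0.001

    def test_exact_matches_scipy_on_clean_data(self, rng):
        # no ties, no zeros: scipy's textbook exact distribution applies
        for _ in range(10):
            d = rng.normal(size=12)
            res = paired_compare(d + 0.3, np.zeros(12) - 0.3 + d + 0.0)
            x = d + 0.3
            y = d - 0.3 + 0.0
            ref = sps.wilcoxon(x, y, method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_approx_path_matches_scipy(self, rng):
        x = rng.normal(size=60)
        y = x + rng.normal(0.2, 1.0, size=60)
        res = paired_compare(x, y, method="asymptotic")
        keep = x != y
        ref = sps.wilcoxon(x[keep], y[keep], correction=True, method="approx")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            paired_compare([1, 2, 3], [1, 2])


class TestKruskal:
    def test_identical_groups_give_h_zero_p_one(self):
        values = [1.0] * 9
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = bmi_compare(values, groups)
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.degenerate

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="groups"):
            bmi_compare([1, 2, 3], ["a", "a", "a"])

    def test_statistic_matches_scipy(self, rng):
        values = rng.normal(size=30)
        groups = rng.choice(["a", "b", "c"], size=30)
        res = bmi_compare(values, groups, method="asymptotic")
        ref = sps.kruskal(*[values[groups == g] for g in ("a", "b", "c")])
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_two_groups_agree_with_mann_whitney_asymptotics(self, rng):
        values = rng.normal(size=40)
        groups = np.array(["a"] * 20 + ["b"] * 20)
        values[groups == "b"] += 0.7
        res = bmi_compare(values, groups, method="asymptotic")
        ref = sps.mannwhitneyu(values[groups == "a"], values[groups == "b"],
                               method="asymptotic", use_continuity=False)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-8)

    def test_power_against_generated_obesity_effect(self):
        # generator's own -16.15-point implant effect is detected at n=300
        from reconpref import generate_latent_profiles, sample_covariates, vas_rate
        from reconpref.cohort import participant_stream
        from reconpref.states import RECON_QUALITIES, build_deck
        from reconpref.validation import recovery_config

        deck = build_deck("normal", "unilateral")
        hits = 0
        reps = 20
        for rep in range(reps):
            config = recovery_config(300).replace(rng_seed=1000 + rep)
            cov = sample_covariates(config)
            profiles = generate_latent_profiles(cov, config)
            scores = []
            for i, p in enumerate(profiles, start=1):
                rng = participant_stream(config.rng_seed, i, 3)
                vas = vas_rate(p, deck, rounding=2.5, rng=rng, anchor=False)
                scores.append(np.mean([vas.rating[f"implant_{q}"]
                                       for q in RECON_QUALITIES]))
            res = bmi_compare(scores, cov["bmi_category"].astype(str))
            hits += res.p_value < 0.05
        assert hits / reps >= 0.9


class TestUnivariateScreen:
    def test_exact_predictor_retained(self, rng):
        x = rng.normal(size=50)
        cov = pd.DataFrame({"x": x, "junk": rng.normal(size=50)})
        res = univariate_screen(2.0 * x, cov)
        assert "x" in res.retained

    def test_constant_covariate_excluded_with_warning(self, rng):
        cov = pd.DataFrame({"flat": np.ones(30), "x": rng.normal(size=30)})
        with pytest.warns(UserWarning, match="zero variance"):
            res = univariate_screen(rng.normal(size=30), cov)
        assert "flat" in res.excluded
        assert "flat" not in res.p_values

    def test_categorical_screened_jointly(self, rng):
        g = rng.choice(["a", "b", "c"], size=90)
        y = rng.normal(size=90) + np.where(g == "c", 2.0, 0.0)
        cov = pd.DataFrame({"g": pd.Categorical(g)})
        res = univariate_screen(y, cov)
        assert res.retained == ["g"]


class TestBackwardAic:
    def test_noise_free_outcome_recovered_to_machine_tolerance(self, rng):
        n = 200
        cov = pd.DataFrame({
            "a": rng.normal(size=n),
            "b": rng.normal(size=n),
        })
        y = 1.5 + 2.0 * cov["a"] - 0.75 * cov["b"]
        model = backward_aic(y, cov)
        assert set(model.retained) == {"a", "b"}
        assert model.terms.loc["a", "coef"] == pytest.approx(2.0, abs=1e-10)
        assert model.terms.loc["b", "coef"] == pytest.approx(-0.75, abs=1e-10)
        assert model.terms.loc["const", "coef"] == pytest.approx(1.5, abs=1e-10)

    def test_strong_effect_survives_noise_covariates(self, rng):
        hits = 0
        reps = 20
        for _ in range(reps):
            n = 500
            cov = pd.DataFrame({f"noise{i}": rng.normal(size=n) for i in range(3)})
            cov["true"] = rng.normal(size=n)
            y = 3.0 * cov["true"] + rng.normal(size=n)
            model = backward_aic(y, cov)
            hits += "true" in model.retained
        assert hits == reps

    def test_null_covariate_usually_dropped(self, rng):
        dropped = 0
        reps = 40
        for _ in range(reps):
            cov = pd.DataFrame({"x": rng.normal(size=400)})
            y = rng.normal(size=400)
            model = backward_aic(y, cov)
            dropped += "x" not in model.retained
        # AIC drops a null covariate when its chi-square deviance gain < 2,
        # i.e. in about 84% of replicates
        assert dropped / reps > 0.6

    def test_collinear_covariate_dropped_with_warning(self, rng):
        cov = pd.DataFrame({"a": rng.normal(size=60)})
        cov["b"] = 2.0 * cov["a"]
        cov["c"] = rng.normal(size=60)
        y = cov["a"] + cov["c"] + rng.normal(size=60) * 0.1
        with pytest.warns(UserWarning, match="collinear"):
            model = backward_aic(y, cov)
        assert len(model.notes) == 1

    def test_ci_contains_coefficient(self, rng):
        cov = pd.DataFrame({"a": rng.normal(size=300)})
        y = 1.0 * cov["a"] + rng.normal(size=300)
        model = backward_aic(y, cov)
        t = model.terms.loc["a"]
        assert t["ci_low"] <= t["coef"] <= t["ci_high"]

    def test_insufficient_sample_rejected(self, rng):
        cov = pd.DataFrame({f"x{i}": rng.normal(size=6) for i in range(5)})
        with pytest.raises(ValueError, match="n > p"):
            backward_aic(rng.normal(size=6), cov)
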