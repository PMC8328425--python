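import numpy as np
import pandas as pd
import pytest
from statsmodels.tools import eval_measures

from oracles import normal_equations_ols
from trapnest.models import (
    Variant,
    aicc,
    fit_multivariate,
    fit_univariate_ladder,
    ols_fit,
    significance_stars,
)

LEVELS = ["home_garden", "park", "community_garden", "green_roof"]


def _ugs(rng, n):
    return pd.Series(rng.choice(LEVELS, n))


class TestOlsFit:
    def test_exact_linear_relationship(self, rng):
        x = rng.uniform(0, 1, 30)
        design = pd.DataFrame({"const": 1.0, "x": x})
        res = ols_fit(2.0 * x + 1.0, design)
        assert res.rsquared == pytest.approx(1.0)
        assert res.ssr == pytest.approx(0.0, abs=1e-20)

    def test_orthogonal_response(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0] * 5)
        y = np.array([1.0, 1.0, -1.0, -1.0] * 5)  # varies, but orthogonal to x
        res = ols_fit(y, pd.DataFrame({"const": 1.0, "x": x}))
        assert res.params[1] == pytest.approx(0.0, abs=1e-12)
        assert res.rsquared == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 3))])
        y = rng.normal(size=20)
        res = ols_fit(y, pd.DataFrame(X, columns=["const", "a", "b", "c"]))
        np.testing.assert_allclose(res.params, normal_equations_ols(X, y), atol=1e-8)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=25)
        design = pd.DataFrame({"const": 1.0, "x": x, "x_copy": x})
        with pytest.raises(np.linalg.LinAlgError, match="x_copy"):
            ols_fit(rng.normal(size=25), design)


class TestAicc:
    def test_closed_form_correction(self):
        # at n=10, k=3 the small-sample correction is 2*3*4/6 = 4
        rss, n, k = 5.0, 10, 3
        aic = n * np.log(rss / n) + n * (np.log(2 * np.pi) + 1) + 2 * k
        assert aicc(rss, n, k) == pytest.approx(aic + 4.0)

    def test_monotone_parameter_penalty(self):
        assert aicc(3.0, 50, 3) < aicc(3.0, 50, 4)

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ValueError):
            aicc(1.0, 5, 4)

    def test_agrees_with_statsmodels_convention(self, rng):
        """Cross-check against the independent statsmodels AICc (computed
        from the Gaussian log-likelihood) under the same k convention."""
        n, k = 40, 4
        rss = float(rng.uniform(1, 10))
        llf = -n / 2 * (np.log(2 * np.pi) + np.log(rss / n) + 1)
        assert aicc(rss, n, k) == pytest.approx(eval_measures.aicc(llf, n, k), rel=1e-12)

    def test_ranking_invariant_to_likelihood_constant(self, rng):
        """AICc differences between two fits don't depend on additive
        likelihood conventions: recompute both with a shifted constant."""
        rss1, rss2, n = 4.0, 3.5, 60
        delta = aicc(rss2, n, 5) - aicc(rss1, n, 3)
        shift = 17.0  # any additive constant cancels in differences
        assert (aicc(rss2, n, 5) + shift) - (aicc(rss1, n, 3) + shift) == pytest.approx(delta)


class TestUnivariateLadder:
    def test_linear_truth_selects_linear(self, rng):
        x = pd.Series(rng.uniform(0, 1, 100))
        y = 2 * x + rng.normal(0, 0.05, 100)
        _, winner = fit_univariate_ladder(x, y, _ugs(rng, 100))
        assert winner.spec.variant == Variant.LINEAR

    def test_quadratic_truth_selects_quadratic(self, rng):
        x = pd.Series(rng.uniform(0, 1, 100))
        y = (x - 0.5) ** 2 * 20 + rng.normal(0, 0.05, 100)
        _, winner = fit_univariate_ladder(x, y, _ugs(rng, 100))
        assert winner.spec.variant == Variant.QUADRATIC

    def test_opposite_slopes_select_interaction(self, rng):
        x = pd.Series(rng.uniform(0, 1, 100))
        ugs = _ugs(rng, 100)
        sign = ugs.map(lambda u: 1.0 if u in ("home_garden", "park") else -1.0)
        y = 3 * sign * x + rng.normal(0, 0.1, 100)
        _, winner = fit_univariate_ladder(x, y, ugs)
        assert winner.spec.variant == Variant.INTERACTION

    def test_sparse_ugs_level_drops_interaction_variants(self, rng):
        n = 40
        ugs = pd.Series(["home_garden"] * (n - 1) + ["green_roof"])
        x = pd.Series(rng.uniform(0, 1, n))
        y = pd.Series(rng.normal(size=n))
        fits, winner = fit_univariate_ladder(x, y, ugs)
        assert {f.spec.variant for f in fits} == {Variant.LINEAR, Variant.QUADRATIC}

    def test_winner_reproducible(self, rng):
        x = pd.Series(rng.uniform(0, 1, 60))
        y = pd.Series(rng.normal(size=60))
        ugs = _ugs(rng, 60)
        a = fit_univariate_ladder(x, y, ugs)[1]
        b = fit_univariate_ladder(x, y, ugs)[1]
        assert a == b

    def test_minimum_sample_size(self, rng):
        with pytest.raises(ValueError):
            fit_univariate_ladder(
                pd.Series(rng.uniform(size=5)), pd.Series(rng.normal(size=5)), _ugs(rng, 5)
            )


class TestMultivariate:
    def test_exact_linear_combination_r2_one(self, rng):
        X = pd.DataFrame(rng.uniform(0, 1, (50, 3)), columns=["a", "b", "c"])
        y = X["a"] + 2 * X["b"] - X["c"]
        fit = fit_multivariate(X, y, {c: Variant.LINEAR for c in X}, _ugs(rng, 50))
        assert fit.r2 == pytest.approx(1.0)

    def test_mixed_term_plan_matches_design_size(self, rng):
        n = 80
        X = pd.DataFrame(rng.uniform(0, 1, (n, 2)), columns=["a", "b"])
        y = pd.Series(rng.normal(size=n))
        ugs = _ugs(rng, n)
        fit = fit_multivariate(
            X, y, {"a": Variant.QUADRATIC, "b": Variant.INTERACTION}, ugs
        )
        # const + (a_c, a_c2) + (b, 3 ugs dummies, 3 slopes) + variance
        assert fit.k == 1 + 2 + 7 + 1

    def test_selection_inflates_null_rejection(self, rng):
        """Choosing terms by AICc and then reading the F-test off the
        selected model is anti-conservative: under a pure-noise null the
        rejection rate exceeds the nominal level by a wide margin. This is
        why reported p-values must be interpreted as conditional on the
        selected terms (no multiple-testing correction is applied)."""
        n, reps = 100, 200
        rejected = 0
        for _ in range(reps):
            X = pd.DataFrame(rng.uniform(0, 1, (n, 3)), columns=["a", "b", "c"])
            y = pd.Series(rng.normal(size=n))
            ugs = _ugs(rng, n)
            plan = {c: fit_univariate_ladder(X[c], y, ugs, name=c)[1].spec.variant for c in X}
            if fit_multivariate(X, y, plan, ugs).p_overall < 0.05:
                rejected += 1
        assert rejected / reps > 0.08  # nominal would be ~0.05 +- 0.015


def test_significance_star_bands():
    assert [significance_stars(p) for p in (0.2, 0.04, 0.009, 0.0009)] == ["", "*", "**", "***"]
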