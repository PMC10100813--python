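"""The statistical battery: rank tests, letters, PCA, GLM suite."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ilta.stats_models import (
    ModelFormula,
    anova_type2,
    fit_glm,
    kruskal_letters,
    mann_whitney,
    pca_traits,
    r2_measures,
    shapiro_wilk,
    stepwise_aic,
)


def brute_force_w(x, y):
    """W = #{x_i > y_j} + half the ties, by direct pair counting."""
    w = 0.0
    for xi, yj in itertools.product(x, y):
        if xi > yj:
            w += 1.0
        elif xi == yj:
            w += 0.5
    return w


class TestMannWhitney:
    def test_all_pairs_less(self):
        assert mann_whitney([1, 2], [3])["W"] == 0.0

    def test_all_pairs_greater(self):
        assert mann_whitney([3], [1, 2])["W"] == 2.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @settings(max_examples=60, deadline=None)
    @given(
        x=st.lists(st.integers(0, 8), min_size=1, max_size=30),
        y=st.lists(st.integers(0, 8), min_size=1, max_size=30),
    )
    def test_matches_brute_force_pair_count(self, x, y):
        assert mann_whitney(x, y)["W"] == brute_force_w(x, y)

    @settings(max_examples=40, deadline=None)
    @given(
        x=st.lists(
            st.floats(0, 100, allow_nan=False), min_size=1, max_size=20,
        ),
        y=st.lists(
            st.floats(0, 100, allow_nan=False), min_size=1, max_size=20,
        ),
    )
    def test_complement_identity(self, x, y):
        w_xy = mann_whitney(x, y)["W"]
        w_yx = mann_whitney(y, x)["W"]
        assert w_xy + w_yx == pytest.approx(len(x) * len(y))


class TestShapiroWilk:
    def test_skewed_sample_rejected_as_normal(self, rng):
        rejections = 0
        for seed in range(50):
            sample = np.exp(
                np.random.default_rng(seed).normal(size=100)
            )
            if shapiro_wilk(sample)["p"] < 0.01:
                rejections += 1
        assert rejections >= 48

    def test_null_pvalues_roughly_uniform(self):
        import scipy.stats

        pvals = [
            shapiro_wilk(np.random.default_rng(seed).normal(size=80))["p"]
            for seed in range(50)
        ]
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])
        with pytest.raises(ValueError):
            shapiro_wilk([3.0] * 10)


class TestKruskalLetters:
    def test_two_separated_groups(self):
        values = list(range(1, 11)) + list(range(101, 111))
        groups = ["g1"] * 10 + ["g2"] * 10
        out = kruskal_letters(values, groups)
        assert out.loc["g1", "letters"] != out.loc["g2", "letters"]
        assert set(out["letters"]) == {"a", "b"}

    def test_identical_groups_share_a_letter(self):
        values = [1, 2, 3, 4, 5] * 2
        groups = ["g1"] * 5 + ["g2"] * 5
        out = kruskal_letters(values, groups)
        assert out.loc["g1", "letters"] == out.loc["g2", "letters"] == "a"

    def test_chain_of_three_groups(self):
        # constructed overlapping sequences: the extremes differ, the
        # middle group is indistinguishable from both neighbours
        low = np.arange(10.0)
        mid = low + 2.0
        high = low + 4.0
        values = np.concatenate([low, mid, high])
        groups = ["low"] * 10 + ["mid"] * 10 + ["high"] * 10
        out = kruskal_letters(values, groups)
        assert out.loc["low", "letters"] == "a"
        assert out.loc["mid", "letters"] == "ab"
        assert out.loc["high", "letters"] == "b"

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_letters([1, 2, 3], ["g"] * 3)


class TestPCA:
    def _frame(self, rng, n=80):
        base = rng.normal(size=n)
        return pd.DataFrame(
            {
                "lma_gm2": base + rng.normal(scale=0.05, size=n),
                "leaf_area_mm2": base + rng.normal(scale=0.05, size=n),
                "leaf_width_mm": rng.normal(size=n),
                "leaf_length_mm": rng.normal(size=n),
                "length_width_ratio": rng.normal(size=n),
            }
        )

    def test_correlated_pair_dominates_pc1(self, rng):
        res = pca_traits(self._frame(rng))
        contribs = res.contributions["PC1"]
        assert contribs["lma_gm2"] == pytest.approx(
            contribs["leaf_area_mm2"], abs=5.0
        )
        assert contribs["lma_gm2"] + contribs["leaf_area_mm2"] > 60.0

    def test_eigenvalues_sum_to_variable_count(self, rng):
        res = pca_traits(self._frame(rng))
        assert res.eigenvalues.sum() == pytest.approx(5.0)
        assert res.variance_explained.sum() == pytest.approx(100.0)

    def test_scores_covariance_diagonal_equals_eigenvalues(self, rng):
        res = pca_traits(self._frame(rng))
        cov = np.cov(res.scores.to_numpy(), rowvar=False)
        assert np.diag(cov) == pytest.approx(res.eigenvalues, rel=1e-8)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_contributions_sum_to_hundred_per_axis(self, rng):
        res = pca_traits(self._frame(rng))
        assert res.contributions.sum(axis=0).to_numpy() == pytest.approx(
            np.full(5, 100.0)
        )

    def test_constant_column_named_in_error(self, rng):
        frame = self._frame(rng)
        frame["length_width_ratio"] = 2.0
        with pytest.raises(ValueError, match="length_width_ratio"):
            pca_traits(frame)

    def test_incomplete_cases_rejected(self, rng):
        frame = self._frame(rng)
        frame.loc[0, "lma_gm2"] = np.nan
        with pytest.raises(ValueError, match="lma_gm2"):
            pca_traits(frame)


def simulate_gamma(seed, n=500, intercept=50.0, slope=10.0, shape=20.0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 5, size=n)
    mu = intercept + slope * x
    y = rng.gamma(shape, mu / shape)
    return pd.DataFrame({"y": y, "x": x, "noise": rng.normal(size=n)})


class TestGLM:
    def test_intercept_only_gamma_recovers_mean(self, rng):
        data = pd.DataFrame({"y": rng.gamma(5.0, 2.0, size=200)})
        res = fit_glm(ModelFormula("y", (), "gamma_identity"), data)
        assert res.coefficients["Intercept"] == pytest.approx(
            data["y"].mean(), rel=1e-6
        )

    def test_uninformative_binary_predictor_has_near_zero_slope(self, rng):
        n = 2000
        data = pd.DataFrame(
            {
                "y": rng.integers(0, 2, size=n),
                "g": np.repeat(["a", "b"], n // 2),
            }
        )
        res = fit_glm(ModelFormula("y", ("g",), "binomial_logit"), data)
        slope = res.coefficients["g[T.b]"]
        se = res.fitted.bse["g[T.b]"]
        assert abs(slope) < 3 * se

    def test_gamma_coefficient_recovery_across_seeds(self):
        """Coefficients fall within 3 SE of generative truth (20 seeds)."""
        hits = 0
        for seed in range(20):
            data = simulate_gamma(seed)
            res = fit_glm(ModelFormula("y", ("x",), "gamma_identity"), data)
            ok = (
                abs(res.coefficients["Intercept"] - 50.0)
                <= 3 * res.fitted.bse["Intercept"]
                and abs(res.coefficients["x"] - 10.0)
                <= 3 * res.fitted.bse["x"]
            )
            hits += ok
        assert hits >= 16

    def test_nonpositive_response_rejected_for_gamma(self):
        data = pd.DataFrame({"y": [1.0, -2.0, 3.0], "x": [1, 2, 3]})
        with pytest.raises(ValueError):
            fit_glm(ModelFormula("y", ("x",), "gamma_identity"), data)

    def test_non_binary_response_rejected_for_binomial(self):
        data = pd.DataFrame({"y": [0, 1, 2], "x": [1, 2, 3]})
        with pytest.raises(ValueError):
            fit_glm(ModelFormula("y", ("x",), "binomial_logit"), data)


class TestStepwise:
    def test_pure_noise_term_dropped(self):
        dropped = 0
        for seed in range(20):
            data = simulate_gamma(seed)
            full = ModelFormula("y", ("x", "noise"), "gamma_identity")
            selected = stepwise_aic(full, data)
            dropped += "noise" not in selected.formula.terms
            assert "x" in selected.formula.terms
        assert dropped >= 11  # noise survives only by chance (~16% per seed)

    def test_selected_aic_never_above_full(self):
        for seed in range(5):
            data = simulate_gamma(seed, n=200)
            full = ModelFormula("y", ("x", "noise"), "gamma_identity")
            full_fit = fit_glm(full, data)
            selected = stepwise_aic(full, data)
            assert selected.aic <= full_fit.aic + 1e-9

    def test_single_term_model_kept_when_no_improvement(self):
        data = simulate_gamma(0)
        res = stepwise_aic(ModelFormula("y", ("x",), "gamma_identity"), data)
        assert res.formula.terms == ("x",)
        assert res.selection_trace[0][0] == "y ~ x"


class TestAnovaAndR2:
    def test_single_term_equals_null_comparison(self):
        data = simulate_gamma(1)
        res = fit_glm(ModelFormula("y", ("x",), "gamma_identity"), data)
        null = fit_glm(ModelFormula("y", (), "gamma_identity"), data)
        table = anova_type2(res, data)
        assert table.loc["x", "lr_chisq"] == pytest.approx(
            2 * (res.loglik - null.loglik), rel=1e-9
        )

    def test_table_rows_match_terms(self):
        data = simulate_gamma(2)
        res = fit_glm(
            ModelFormula("y", ("x", "noise"), "gamma_identity"), data,
        )
        table = anova_type2(res, data)
        assert list(table.index) == ["x", "noise"]

    def test_null_term_pvalues_uniform(self):
        import scipy.stats

        pvals = []
        for seed in range(50):
            data = simulate_gamma(seed, n=300)
            res = fit_glm(
                ModelFormula("y", ("x", "noise"), "gamma_identity"), data,
            )
            pvals.append(anova_type2(res, data).loc["noise", "p"])
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_null_model_r2_is_zero(self):
        data = simulate_gamma(3)
        res = fit_glm(ModelFormula("y", (), "gamma_identity"), data)
        assert r2_measures(res, data)["nagelkerke"] == pytest.approx(
            0.0, abs=1e-9
        )

    def test_tjur_equals_hand_computation(self, rng):
        n = 400
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.5 + 1.5 * x)))
        y = (rng.random(n) < p).astype(int)
        data = pd.DataFrame({"y": y, "x": x})
        res = fit_glm(ModelFormula("y", ("x",), "binomial_logit"), data)
        out = r2_measures(res, data)
        mu = np.asarray(res.fitted.fittedvalues)
        hand = mu[y == 1].mean() - mu[y == 0].mean()
        assert out["tjur"] == pytest.approx(hand, rel=1e-9)
        assert 0 < out["tjur"] < 1

    def test_near_separation_pushes_tjur_toward_one(self, rng):
        n = 200
        x = np.concatenate([rng.normal(-8, 1, n // 2),
                            rng.normal(8, 1, n // 2)])
        y = (x > 0).astype(int)
        data = pd.DataFrame({"y": y, "x": x})
        res = fit_glm(ModelFormula("y", ("x",), "binomial_logit"), data)
        assert r2_measures(res, data)["tjur"] > 0.95
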