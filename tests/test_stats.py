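"""Transforms, collinearity screen, AICc, mixed-model fitting, all-subsets
selection and proportion-scale effect sizes, checked against closed forms
and simulated data with known generating parameters."""

import numpy as np
import pandas as pd
import pytest

from greenwave.stats import (
    ModelFitResult,
    TransformSpec,
    aicc,
    all_subsets_selection,
    apply_transforms,
    correlation_screen,
    effect_size_proportion,
    fit_lmm,
    r2_nakagawa,
)


class TestTransforms:
    def test_log_and_asin_sqrt_closed_forms(self):
        table = pd.DataFrame({"e": [1.0, np.e, np.e ** 2], "p": [0.0, 0.25, 1.0]})
        spec = TransformSpec(transforms={"e": "log", "p": "asin_sqrt"})
        out = apply_transforms(table, spec)
        np.testing.assert_allclose(out["e"], [0.0, 1.0, 2.0])
        # asin(sqrt(0.25)) = asin(0.5) = pi/6; boundaries map to 0 and pi/2
        np.testing.assert_allclose(out["p"], [0.0, np.pi / 6, np.pi / 2])

    def test_standardize_stores_constants(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        spec = TransformSpec(transforms={}, standardize=("x",))
        out = apply_transforms(table, spec)
        assert spec.means["x"] == pytest.approx(2.5)
        assert spec.sds["x"] == pytest.approx(np.std([1, 2, 3, 4], ddof=1))
        assert out["x"].mean() == pytest.approx(0.0)
        assert out["x"].std(ddof=1) == pytest.approx(1.0)

    def test_input_table_not_mutated(self):
        table = pd.DataFrame({"x": [1.0, 2.0]})
        apply_transforms(table, TransformSpec(transforms={"x": "log"}))
        np.testing.assert_allclose(table["x"], [1.0, 2.0])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            apply_transforms(pd.DataFrame({"x": [1.0, -2.0]}),
                             TransformSpec(transforms={"x": "log"}))
        with pytest.raises(ValueError, match="proportion"):
            apply_transforms(pd.DataFrame({"p": [0.5, 1.2]}),
                             TransformSpec(transforms={"p": "asin_sqrt"}))
        with pytest.raises(ValueError, match="constant"):
            apply_transforms(pd.DataFrame({"x": [2.0, 2.0]}),
                             TransformSpec(transforms={}, standardize=("x",)))
        with pytest.raises(ValueError, match="unknown"):
            apply_transforms(pd.DataFrame({"x": [1.0]}),
                             TransformSpec(transforms={"x": "sqrt"}))


class TestCorrelationScreen:
    def test_near_duplicate_resolved_by_relevance(self, rng):
        x = rng.normal(size=200)
        table = pd.DataFrame({
            "keep_me": x,
            "shadow": x + rng.normal(0, 0.05, 200),  # |r| ~ 0.999
            "independent": rng.normal(size=200),
        })
        retained, log = correlation_screen(
            table, ["keep_me", "shadow", "independent"],
            relevance=["keep_me", "independent", "shadow"])
        assert retained == ["keep_me", "independent"]
        assert log[0]["dropped"] == "shadow"
        assert log[0]["r"] > 0.99

    def test_uncorrelated_covariates_all_retained(self, rng):
        table = pd.DataFrame(rng.normal(size=(300, 3)), columns=list("abc"))
        retained, log = correlation_screen(table, ["a", "b", "c"],
                                           relevance=["a", "b", "c"])
        assert retained == ["a", "b", "c"]
        assert log == []

    def test_constant_column_does_not_poison_screen(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=50), "flat": np.ones(50)})
        retained, _ = correlation_screen(table, ["a", "flat"],
                                         relevance=["a", "flat"])
        assert retained == ["a", "flat"]

    def test_missing_relevance_entry_rejected(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10)})
        with pytest.raises(ValueError, match="relevance"):
            correlation_screen(table, ["a", "b"], relevance=["a"])


class TestAICc:
    def test_published_identity(self):
        # printed model summary: loglik -1362.8, df 8, n 340 -> AICc 2742.1
        assert aicc(-1362.8, 8, 340) == pytest.approx(2742.1, abs=0.2)

    def test_reduces_to_aic_for_large_n(self):
        aic = -2 * (-100.0) + 2 * 8
        assert abs(aicc(-100.0, 8, 10 ** 6) - aic) < 0.01

    def test_correction_term_closed_form(self):
        # AICc - AIC = 2 df (df + 1) / (n - df - 1)
        assert aicc(0.0, 3, 20) - (2 * 3) == pytest.approx(2 * 3 * 4 / 16)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            aicc(0.0, 8, 9)


def _mixed_data(rng, n=400, n_years=8, beta=(10.0, 2.0, -1.0),
                year_sd=3.0, resid_sd=5.0):
    years = 2005 + rng.integers(0, n_years, n)
    year_eff = dict(zip(range(2005, 2005 + n_years),
                        rng.normal(0, year_sd, n_years)))
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    y = (beta[0] + beta[1] * x1 + beta[2] * x2
         + np.array([year_eff[yr] for yr in years])
         + rng.normal(0, resid_sd, n))
    return pd.DataFrame({"y": y, "x1": x1, "x2": x2, "year": years})


class TestFitLMM:
    def test_recovers_known_generating_parameters(self):
        rng = np.random.default_rng(99)
        table = _mixed_data(rng)
        fit = fit_lmm(table, "y", ["x1", "x2"])
        for name, truth in [("x1", 2.0), ("x2", -1.0)]:
            assert abs(fit.estimates[name] - truth) < 2 * fit.se[name]
        assert fit.resid_sd == pytest.approx(5.0, rel=0.15)
        assert 1.0 < fit.year_sd < 6.0  # 8 group levels: noisy but positive
        assert not fit.boundary_flag
        assert fit.df == 5  # intercept + 2 slopes + 2 variance components

    def test_zero_group_variance_hits_boundary(self):
        rng = np.random.default_rng(3)
        table = _mixed_data(rng, year_sd=0.0)
        fit = fit_lmm(table, "y", ["x1", "x2"])
        assert fit.boundary_flag
        assert fit.year_sd == pytest.approx(0.0, abs=0.5)
        r2m, r2c = r2_nakagawa(fit)
        assert r2c == pytest.approx(r2m, abs=0.02)

    def test_intercept_only_matches_ols_boundary_oracle(self):
        rng = np.random.default_rng(11)
        table = _mixed_data(rng, year_sd=0.0)
        fit = fit_lmm(table, "y", [])
        import statsmodels.formula.api as smf

        ols = smf.ols("y ~ 1", data=table).fit()
        # the mixed loglik can only improve on the zero-variance boundary
        assert fit.loglik >= float(ols.llf) - 1e-8
        assert fit.df == 3
        assert fit.estimates["Intercept"] == pytest.approx(table["y"].mean(), abs=1.0)

    def test_r2_increases_with_informative_fixed_effect(self):
        rng = np.random.default_rng(21)
        table = _mixed_data(rng, beta=(0.0, 10.0, 0.0), resid_sd=1.0)
        null = fit_lmm(table, "y", [])
        full = fit_lmm(table, "y", ["x1"])
        assert null.r2_marginal == pytest.approx(0.0, abs=1e-9)
        assert full.r2_marginal > 0.9
        assert full.r2_conditional >= full.r2_marginal

    def test_missing_values_rejected(self):
        table = pd.DataFrame({"y": [1.0, np.nan, 2.0, 1.5],
                              "x1": [0.0, 1.0, 2.0, 3.0],
                              "year": [2005, 2005, 2006, 2006]})
        with pytest.raises(ValueError, match="missing"):
            fit_lmm(table, "y", ["x1"])

    def test_single_group_rejected(self):
        table = pd.DataFrame({"y": [1.0, 2.0, 3.0], "year": [2005] * 3})
        with pytest.raises(ValueError, match="2 group"):
            fit_lmm(table, "y", [])


@pytest.fixture(scope="module")
def strong_signal():
    rng = np.random.default_rng(7)
    n = 300
    table = pd.DataFrame({
        "a": rng.normal(size=n),
        "b": rng.normal(size=n),
        "c": rng.normal(size=n),
        "year": 2005 + rng.integers(0, 6, n),
    })
    table["y"] = 5.0 + 3.0 * table["a"] - 2.0 * table["b"] \
        + 1.5 * table["a"] * table["b"] + rng.normal(0, 1.0, n)
    return table


class TestAllSubsets:
    def test_recovers_generating_structure(self, strong_signal):
        res = all_subsets_selection(strong_signal, "y", ["a", "b", "c"],
                                    interactions=[("a", "b")])
        assert set(res.preferred.terms) == {"a", "b", "a:b"}
        assert res.preferred.estimates["a"] == pytest.approx(3.0, abs=0.3)
        assert res.preferred.estimates["a:b"] == pytest.approx(1.5, abs=0.3)

    def test_marginality_no_orphan_interactions(self, strong_signal):
        res = all_subsets_selection(strong_signal, "y", ["a", "b", "c"],
                                    interactions=[("a", "b")])
        for terms in (f.terms for f in res.fits):
            if "a:b" in terms:
                assert "a" in terms and "b" in terms
        # 2^3 main subsets + the 2 that admit a:b ({a,b} and {a,b,c})
        assert len(res.fits) == 10

    def test_weights_sum_to_one_and_rank_matches_aicc(self, strong_signal):
        res = all_subsets_selection(strong_signal, "y", ["a", "b", "c"])
        assert res.table["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        assert res.table["aicc"].is_monotonic_increasing
        assert res.table["delta_aic"].iloc[0] == 0.0
        fit_order = [f.aicc for f in res.fits]
        assert fit_order == sorted(fit_order)

    def test_competitive_set_uses_delta_two(self, strong_signal):
        res = all_subsets_selection(strong_signal, "y", ["a", "b", "c"],
                                    interactions=[("a", "b")])
        deltas = res.table["delta_aic"].to_numpy()
        assert len(res.competitive) == int((deltas < 2.0).sum())
        assert res.preferred in res.competitive

    def test_ranking_invariant_to_covariate_standardization(self, strong_signal):
        scaled = strong_signal.copy()
        scaled["a"] = (scaled["a"] - scaled["a"].mean()) / scaled["a"].std(ddof=1)
        raw = all_subsets_selection(strong_signal, "y", ["a", "b", "c"])
        std = all_subsets_selection(scaled, "y", ["a", "b", "c"])
        assert list(raw.table["terms"]) == list(std.table["terms"])
        np.testing.assert_allclose(raw.table["aicc"], std.table["aicc"], atol=1e-5)


def _manual_fit(beta, covariate="prop_forest"):
    est = pd.Series({"Intercept": 50.0, covariate: beta})
    ones = pd.Series(1.0, index=est.index)
    return ModelFitResult(terms=(covariate,), estimates=est, se=ones,
                          tvalues=est, pvalues=ones, year_sd=0.0, resid_sd=1.0,
                          loglik=0.0, aicc=0.0, df=3, n=10,
                          r2_marginal=0.0, r2_conditional=0.0)


class TestEffectSizeProportion:
    SPEC = TransformSpec(transforms={"prop_forest": "asin_sqrt"})

    def test_single_animal_closed_form(self):
        # beta = -29.50 on the arcsine-sqrt scale, p = 0.25, delta = 0.10:
        # |change| = 29.5 * (asin(sqrt(0.35)) - asin(sqrt(0.25))) ~ 3.23
        table = pd.DataFrame({"prop_forest": [0.25]})
        out = effect_size_proportion(_manual_fit(-29.50), "prop_forest",
                                     table, self.SPEC, delta=0.10)
        expected = 29.5 * (np.arcsin(np.sqrt(0.35)) - np.arcsin(np.sqrt(0.25)))
        assert out["mean"] == pytest.approx(expected, rel=1e-12)
        assert out["mean"] == pytest.approx(3.23, abs=0.01)
        assert out["sign"] == -1.0
        assert out["n_excluded"] == 0

    def test_zero_coefficient_gives_zero_effect(self):
        table = pd.DataFrame({"prop_forest": [0.1, 0.4, 0.8]})
        out = effect_size_proportion(_manual_fit(0.0), "prop_forest",
                                     table, self.SPEC)
        assert out["mean"] == 0.0
        assert out["max"] == 0.0

    def test_magnitude_decreases_toward_mid_proportions(self):
        # the arcsine-sqrt derivative is largest near the 0/1 boundaries,
        # so a +0.10 step moves CIRG more at p=0.85 than at p=0.45
        table = pd.DataFrame({"prop_forest": [0.45, 0.85]})
        fit = _manual_fit(-10.0)
        lo = effect_size_proportion(fit, "prop_forest",
                                    pd.DataFrame({"prop_forest": [0.45]}), self.SPEC)
        hi = effect_size_proportion(fit, "prop_forest",
                                    pd.DataFrame({"prop_forest": [0.85]}), self.SPEC)
        assert hi["mean"] > lo["mean"]
        both = effect_size_proportion(fit, "prop_forest", table, self.SPEC)
        assert both["min"] == pytest.approx(lo["mean"])
        assert both["max"] == pytest.approx(hi["mean"])

    def test_rows_too_close_to_one_excluded(self):
        table = pd.DataFrame({"prop_forest": [0.5, 0.95, np.nan]})
        out = effect_size_proportion(_manual_fit(1.0), "prop_forest",
                                     table, self.SPEC, delta=0.10)
        assert out["n_excluded"] == 2

    def test_standardization_is_undone(self):
        table = pd.DataFrame({"prop_forest": [0.25]})
        spec = TransformSpec(transforms={"prop_forest": "asin_sqrt"},
                             standardize=("prop_forest",),
                             sds={"prop_forest": 2.0})
        # stored sd 2.0: the raw-scale coefficient is beta / 2
        out = effect_size_proportion(_manual_fit(-10.0), "prop_forest",
                                     table, spec)
        base = effect_size_proportion(_manual_fit(-5.0), "prop_forest",
                                      table, self.SPEC)
        assert out["mean"] == pytest.approx(base["mean"], rel=1e-12)

    def test_non_proportion_covariate_rejected(self):
        with pytest.raises(ValueError, match="arcsine"):
            effect_size_proportion(_manual_fit(1.0, "elev"), "elev",
                                   pd.DataFrame({"elev": [0.2]}),
                                   TransformSpec(transforms={"elev": "log"}))
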