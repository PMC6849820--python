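"""Multilevel REML/ML meta-regression: oracles, invariants, CIs."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rangemeta.meta_model import (
    MetaRegression,
    ModeratorTransform,
    RandomEffectsSpec,
    _MarginalLikelihood,
    fit_meta_model,
    report_overall_effect,
    transform_moderators,
)

from conftest import balanced_one_way


class TestModeratorTransform:
    def test_log_center_scale_on_geometric_sequence(self):
        df = pd.DataFrame({"amount_applied": [1.0, math.e, math.e**2]})
        out, tr = transform_moderators(df, ["amount_applied"])
        assert np.allclose(out["amount_applied"], [-1.0, 0.0, 1.0])

    def test_transformed_columns_have_mean_zero_sd_one(self, small_effects):
        effects, _, _ = small_effects
        out, _ = transform_moderators(effects, ["amount_applied", "amendment_n"])
        for col in ("amount_applied", "amendment_n"):
            assert out[col].mean() == pytest.approx(0.0, abs=1e-10)
            assert out[col].std(ddof=1) == pytest.approx(1.0, rel=1e-10)

    def test_stored_stats_reused_not_refit(self):
        df = pd.DataFrame({"amount_applied": [1.0, math.e, math.e**2]})
        _, tr = transform_moderators(df, ["amount_applied"])
        new = tr.transform(pd.DataFrame({"amount_applied": [math.e]}))
        assert new["amount_applied"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [[1.0, 0.0, 2.0], [5.0, 5.0, 5.0]])
    def test_nonpositive_or_constant_columns_error(self, bad):
        with pytest.raises(ValueError):
            transform_moderators(pd.DataFrame({"amount_applied": bad}), ["amount_applied"])


def _intercept_model(y, codes, **kw):
    return MetaRegression(y, np.ones((len(y), 1)), {"experiment": codes},
                          exog_names=["intercept"], **kw)


class TestREMLOracle:
    def test_constant_effect_sizes_recover_constant_with_zero_variance(self):
        y = np.full(24, 0.2927)
        fit = _intercept_model(y, np.repeat(np.arange(6), 4)).fit()
        assert fit.params["intercept"] == pytest.approx(0.2927, abs=1e-8)
        assert all(s2 <= 1e-6 for s2 in fit.sigma2.values())

    @pytest.mark.parametrize("seed", range(10))
    def test_balanced_one_way_matches_anova_reml(self, seed):
        y, codes, oracle, mu = balanced_one_way(10, 4, seed=seed)
        fit = _intercept_model(y, codes).fit()
        assert fit.sigma2["experiment"] == pytest.approx(oracle["between"], abs=1e-6)
        assert fit.sigma2["residual"] == pytest.approx(oracle["within"], abs=1e-6)
        assert fit.params["intercept"] == pytest.approx(mu, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_restricted_likelihood_beats_random_feasible_points(self, seed):
        rng = np.random.default_rng(100 + seed)
        sizes = rng.integers(2, 6, size=6)
        codes = np.repeat(np.arange(6), sizes)
        y = rng.normal(0.3, 0.3, size=len(codes))
        model = _intercept_model(y, codes)
        fit = model.fit()
        lik = _MarginalLikelihood(model.endog, model.exog, model.group_codes, reml=True)
        at_opt = lik.loglik(np.array(list(fit.sigma2.values())))[0]
        for _ in range(64):
            s2 = rng.uniform(0.0, 2.0 * np.var(y), size=2)
            cand = lik.loglik(s2)
            assert cand is None or cand[0] <= at_opt + 1e-6

    def test_ml_loglik_monotone_under_fixed_effect_nesting(self, small_effects):
        effects, _, _ = small_effects
        sub = fit_meta_model(effects, ("amount_applied",), method="ML")
        full = fit_meta_model(effects, ("amount_applied", "amendment_n"), method="ML")
        null = fit_meta_model(effects, (), method="ML")
        assert full.llf >= sub.llf - 1e-6 >= null.llf - 2e-6

    def test_row_permutation_leaves_estimates_unchanged(self, small_effects):
        effects, _, _ = small_effects
        shuffled = effects.sample(frac=1.0, random_state=5)
        a = fit_meta_model(effects, ("amount_applied",))
        b = fit_meta_model(shuffled, ("amount_applied",))
        assert np.allclose(a.params, b.params, atol=1e-10)
        assert a.llf == pytest.approx(b.llf, abs=1e-10)

    def test_simulation_recovers_known_parameters(self):
        """Estimates on model-simulated data sit within 3 MC SEs of truth."""
        rng = np.random.default_rng(11)
        beta0, s_exp, s_res, reps = 0.3, 0.25, 0.15, 40
        est = []
        for _ in range(reps):
            u = rng.normal(0, s_exp, 30)
            codes = np.repeat(np.arange(30), 5)
            y = beta0 + u[codes] + rng.normal(0, s_res, len(codes))
            est.append(_intercept_model(y, codes).fit().params["intercept"])
        mc_se = np.std(est, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(est) - beta0) < 3 * mc_se


class TestWeightingModes:
    def test_inverse_variance_mode_uses_sampling_variances(self, small_effects):
        effects, _, _ = small_effects
        uw = fit_meta_model(effects, ())
        iv = fit_meta_model(effects, (), weighting="inverse_variance")
        # the weighted fit must differ and shrink the residual component,
        # part of which is absorbed by the known sampling variances
        assert iv.sigma2["residual"] < uw.sigma2["residual"]

    def test_unknown_weighting_rejected(self, small_effects):
        effects, _, _ = small_effects
        with pytest.raises(ValueError):
            fit_meta_model(effects, (), weighting="bogus")


class TestWaldCI:
    def test_zero_se_gives_degenerate_interval(self):
        y = np.full(12, 0.5)
        fit = _intercept_model(y, np.repeat(np.arange(4), 3)).fit()
        lo, hi = fit.wald_ci("intercept")
        assert lo == pytest.approx(hi, abs=1e-5) and lo == pytest.approx(0.5, abs=1e-5)

    def test_hand_computed_interval(self):
        """0.2927 +/- 1.959964 * 0.05 -> (0.1947, 0.3907)."""
        y, codes, *_ = balanced_one_way(8, 4, seed=3)
        fit = _intercept_model(y, codes).fit()
        fit.params["intercept"] = 0.2927
        fit.cov_params.iloc[0, 0] = 0.05**2
        lo, hi = fit.wald_ci("intercept", 0.95)
        assert (lo, hi) == (pytest.approx(0.1947, abs=1e-4), pytest.approx(0.3907, abs=1e-4))

    def test_interval_widens_with_level(self):
        y, codes, *_ = balanced_one_way(8, 4, seed=4)
        fit = _intercept_model(y, codes).fit()
        lo95, hi95 = fit.wald_ci("intercept", 0.95)
        lo999, hi999 = fit.wald_ci("intercept", 0.999999)
        assert lo999 < lo95 < hi95 < hi999

    def test_unknown_coefficient_errors(self):
        y, codes, *_ = balanced_one_way(8, 4, seed=4)
        fit = _intercept_model(y, codes).fit()
        with pytest.raises(KeyError):
            fit.wald_ci("amount_applied")


class TestOverallEffectReport:
    def test_ratio_scale_is_exponentiated(self):
        y, codes, *_ = balanced_one_way(8, 4, seed=6)
        fit = _intercept_model(y, codes).fit()
        fit.params["intercept"] = 0.2927
        rep = report_overall_effect(fit)
        assert rep["ratio"] == pytest.approx(1.34, abs=0.005)

    def test_interval_ends_map_through_exp(self):
        y, codes, *_ = balanced_one_way(8, 4, seed=6)
        fit = _intercept_model(y, codes).fit()
        fit.params["intercept"] = 0.2595  # midpoint of (-0.174, 0.693)
        fit.cov_params.iloc[0, 0] = ((0.693 - (-0.174)) / (2 * 1.959964)) ** 2
        rep = report_overall_effect(fit)
        assert rep["ratio_ci"][0] == pytest.approx(math.exp(-0.174), abs=2e-3)
        assert rep["ratio_ci"][1] == pytest.approx(math.exp(0.693), abs=2e-3)

    def test_zero_lnrr_is_ratio_one(self):
        y = np.full(12, 0.0) + np.tile([-0.01, 0.01, 0.0], 4)
        fit = _intercept_model(y, np.repeat(np.arange(4), 3)).fit()
        fit.params["intercept"] = 0.0
        assert report_overall_effect(fit)["ratio"] == 1.0


def test_moderator_spec_term_selection():
    from rangemeta.meta_model import ModeratorSpec

    spec = ModeratorSpec()
    assert "climate_zone" in spec.main_terms(include_climate=True)
    assert "climate_zone" not in spec.main_terms(include_climate=False)
    assert "soil_depth" in spec.main_terms(include_depth=True)
    assert "soil_depth" in spec.covariate_only


class TestModelStructure:
    def test_publication_codes_nest_within_experiment(self):
        df = pd.DataFrame(
            {
                "experiment_id": ["e1", "e1", "e2", "e2"],
                "publication_id": ["p1", "p2", "p1", "p2"],  # reused labels
            }
        )
        codes = RandomEffectsSpec().factors(df)
        # publication p1 in e1 differs from p1 in e2 once nested
        assert len(np.unique(codes["publication"])) == 4

    def test_rank_deficient_design_is_rejected(self, small_effects):
        effects, _, _ = small_effects
        dup = effects.copy()
        dup["amount_copy"] = dup["amount_applied"]
        tr = ModeratorTransform().fit(dup, ["amount_applied", "amount_copy"])
        data = tr.transform(dup)
        from rangemeta.meta_model import build_design

        X, names = build_design(data, ("amount_applied", "amount_copy"))
        with pytest.raises(ValueError, match="rank deficient|collinear"):
            MetaRegression(dup["lnrr"], X, {"experiment": dup["experiment_id"]},
                           exog_names=names)

    def test_single_level_random_factor_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2 levels"):
            MetaRegression(np.zeros(4), np.ones((4, 1)), {"experiment": [0, 0, 0, 0]})
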