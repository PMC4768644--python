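"""Comparative hierarchical models: logit transform, contribution models,
boom test, association test."""

import numpy as np
import pandas as pd
import pytest

from transientmpm import (
    McmcConfig,
    association_test,
    boom_test,
    fit_contribution_model,
    logit_transform,
)
from transientmpm.exceptions import ValidationError
from transientmpm.synthetic import null_summaries

FAST_GIBBS = McmcConfig(iterations=20_000, burn_in_fraction=0.1, thinning=10,
                        backend="gibbs", seed=3)


class TestLogitTransform:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (0.5, 0.0),
            (0.75, np.log(3.0)),
            (1.0, np.log((1 - 1e-6) / 1e-6)),
            (0.0, -np.log((1 - 1e-6) / 1e-6)),
        ],
    )
    def test_known_values(self, p, expected):
        assert logit_transform(p) == pytest.approx(expected, abs=1e-9)

    def test_domain_error(self):
        with pytest.raises(ValidationError):
            logit_transform(1.5)
        with pytest.raises(ValidationError):
            logit_transform(-0.1)

    def test_strictly_increasing_and_odd(self):
        grid = np.linspace(1e-6, 1 - 1e-6, 101)
        vals = logit_transform(grid)
        assert np.all(np.diff(vals) > 0)
        np.testing.assert_allclose(
            logit_transform(grid), -logit_transform(1.0 - grid), atol=1e-9
        )


def synthetic_summaries(seed=0, n_species=25, beta_dim=0.2, species_sd=0.3,
                        resid_sd=0.3, n_pops=2):
    """Summaries with a known logit-scale dimension slope injected directly."""
    rng = np.random.default_rng(seed)
    forms = ["herbaceous_perennial", "shrub", "succulent", "palm", "tree"]
    rows = []
    for i in range(n_species):
        sid = f"s{i:03d}"
        form = forms[i % 5]
        dim = int(rng.integers(2, 12))
        sp = rng.normal(0, species_sd)
        for p in range(n_pops):
            eta = -1.0 + beta_dim * dim + sp + rng.normal(0, resid_sd)
            prop = 1.0 / (1.0 + np.exp(-eta))
            react = rng.normal(0, 0.02)
            rows.append(
                dict(
                    population_id=f"{sid}_p{p}",
                    species_id=sid,
                    growth_form=form,
                    matrix_dimension=dim,
                    n_replicates_used=1000,
                    r2_asym=prop,
                    r2_trans=prop,
                    prop_abs_trans=prop,
                    mean_log_lambda_obs=react + rng.normal(0, 0.02),
                    mean_log_lambda_max=rng.normal(0, 0.05),
                    mean_log_reactivity=react,
                )
            )
    return pd.DataFrame(rows)


class TestContributionModel:
    def test_recovers_injected_dimension_slope(self):
        """95% intervals cover the injected slope in most syntheses and the
        slope is always flagged important."""
        covered = 0
        for seed in range(5):
            summ = synthetic_summaries(seed=seed)
            fit = fit_contribution_model(summ, "prop_abs_trans")
            row = fit.params.loc["matrix_dimension"]
            covered += row["lower95"] <= 0.2 <= row["upper95"]
            assert row["important"] and row["mean"] > 0
        assert covered >= 4

    def test_backends_agree(self):
        summ = synthetic_summaries(seed=2)
        f_ml = fit_contribution_model(summ, "prop_abs_trans")
        f_gb = fit_contribution_model(summ, "prop_abs_trans", FAST_GIBBS)
        np.testing.assert_allclose(
            f_ml.params["mean"], f_gb.params["mean"], atol=0.08
        )

    def test_constant_response_degenerate(self):
        summ = synthetic_summaries(seed=3)
        summ["prop_abs_trans"] = 0.5
        fit = fit_contribution_model(summ, "prop_abs_trans")
        row = fit.params.loc["matrix_dimension"]
        assert abs(row["mean"]) < 1e-6
        assert fit.variance_components["species"] == pytest.approx(0.0, abs=1e-8)

    def test_permutation_invariance(self):
        summ = synthetic_summaries(seed=4)
        f1 = fit_contribution_model(summ, "r2_trans")
        f2 = fit_contribution_model(summ.sample(frac=1.0, random_state=9), "r2_trans")
        np.testing.assert_allclose(f1.params["mean"], f2.params["mean"], atol=1e-6)

    def test_species_relabeling_invariance(self):
        summ = synthetic_summaries(seed=5)
        relabeled = summ.copy()
        relabeled["species_id"] = "x_" + relabeled["species_id"]
        f1 = fit_contribution_model(summ, "r2_asym")
        f2 = fit_contribution_model(relabeled, "r2_asym")
        np.testing.assert_allclose(f1.params["mean"], f2.params["mean"], atol=1e-9)

    def test_single_growth_form_warns_and_drops(self):
        summ = synthetic_summaries(seed=6)
        summ["growth_form"] = "tree"
        with pytest.warns(UserWarning, match="single growth form"):
            fit = fit_contribution_model(summ, "prop_abs_trans")
        assert list(fit.params.index) == ["intercept", "matrix_dimension"]

    def test_validation(self):
        summ = synthetic_summaries(seed=7)
        with pytest.raises(ValidationError):
            fit_contribution_model(summ, "mean_log_reactivity")
        with pytest.raises(ValidationError):
            fit_contribution_model(summ.iloc[:1], "r2_asym")

    def test_ols_oracle_without_random_effect(self):
        """With one population per species and (numerically) no species
        variance, estimates match an ordinary linear model to 3 sig figs."""
        import statsmodels.api as sm

        summ = synthetic_summaries(seed=8, species_sd=0.0, n_pops=1, n_species=60)
        fit = fit_contribution_model(summ, "prop_abs_trans")
        from transientmpm.stats import _contribution_design

        X, L, names = _contribution_design(summ)
        y = logit_transform(summ["prop_abs_trans"].to_numpy())
        ols = sm.OLS(y, X).fit()
        expected = L @ ols.params
        np.testing.assert_allclose(fit.params["mean"], expected, rtol=2e-3)


class TestBoomTest:
    def test_separated_case(self):
        summ = null_summaries(intercept=0.05, species_sd=0.005, residual_sd=0.005, seed=1)
        fit = boom_test(summ)
        row = fit.params.loc["intercept"]
        assert row["important"] and row["lower95"] > 0
        assert fit.pmcmc < 0.05

    def test_sign_flip_symmetry(self):
        summ = null_summaries(intercept=0.02, seed=2)
        flipped = summ.copy()
        flipped["mean_log_reactivity"] *= -1.0
        f1, f2 = boom_test(summ), boom_test(flipped)
        assert f1.params.loc["intercept", "mean"] == pytest.approx(
            -f2.params.loc["intercept", "mean"], abs=1e-9
        )
        w1 = f1.params.loc["intercept", "upper95"] - f1.params.loc["intercept", "lower95"]
        w2 = f2.params.loc["intercept", "upper95"] - f2.params.loc["intercept", "lower95"]
        assert w1 == pytest.approx(w2, abs=1e-9)

    def test_gibbs_interval_and_pmcmc(self):
        summ = null_summaries(intercept=0.05, species_sd=0.005, residual_sd=0.005, seed=4)
        fit = boom_test(summ, cfg=FAST_GIBBS)
        assert fit.params.loc["intercept", "lower95"] > 0
        assert fit.pmcmc < 0.05
        assert fit.diagnostics["max_lag1_autocorr"] < 0.1


class TestAssociationTest:
    def test_exact_identity_slope(self):
        summ = null_summaries(intercept=0.0, seed=5)
        summ["mean_log_lambda_obs"] = summ["mean_log_reactivity"]
        fit = association_test(summ)
        assert fit.params.loc["slope", "mean"] == pytest.approx(1.0, abs=1e-3)

    def test_strong_link_rejected_null(self):
        rejections = 0
        for s in range(5):
            summ = null_summaries(intercept=0.0, residual_sd=0.02, seed=100 + s)
            summ["mean_log_lambda_obs"] = (
                summ["mean_log_reactivity"]
                + np.random.default_rng(s).normal(0, 0.005, len(summ))
            )
            fit = association_test(summ)
            rejections += fit.lrt_p < 0.05
        assert rejections == 5

    def test_interval_semantics(self):
        summ = null_summaries(seed=6)
        fit = association_test(summ)
        row = fit.params.loc["slope"]
        assert row["lower95"] <= row["mean"] <= row["upper95"]
        assert bool(row["important"]) == (not row["lower95"] <= 0 <= row["upper95"])
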