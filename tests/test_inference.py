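"""The multilevel binomial model: design construction, estimation oracles,
effect translations, marginal effects, model comparison, recovery."""

import json
import shutil
import subprocess
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from masktrends.inference import (
    MaskMandateGLMM,
    build_design,
    compare_models,
    effect_per_sd,
    marginal_effect_curve,
    recovery_study,
)
from masktrends.synthetic_data import GeneratorParams, simulate_panel


class TestDesign:
    def test_default_panel_is_300_by_22(self):
        panel = simulate_panel(GeneratorParams(seed=2))
        d = build_design(panel)
        assert d.X.shape == (6600, 10)
        assert d.y.shape == (6600,)
        assert {f: len(v) for f, v in d.group_levels.items()} == {
            "county": 300, "state": 45, "week": 22,
        }

    def test_interaction_column_is_elementwise_product(self, small_panel):
        d = build_design(small_panel, interaction=True)
        i_m, i_g, i_mg = (d.exog_names.index(t) for t in ("mandate", "gop", "mandate_gop"))
        assert np.allclose(d.X[:, i_mg], d.X[:, i_m] * d.X[:, i_g])

    def test_dropping_interaction_removes_one_column(self, small_panel):
        with_ = build_design(small_panel, interaction=True)
        without = build_design(small_panel, interaction=False)
        assert with_.X.shape[1] - without.X.shape[1] == 1
        assert "mandate_gop" not in without.exog_names

    def test_zero_trial_rows_rejected_with_instruction(self, small_panel):
        bad = small_panel.copy()
        bad.loc[bad.index[0], "n_image_users"] = 0
        with pytest.raises(ValueError, match="exclude"):
            build_design(bad)


class TestEstimation:
    def test_reduction_to_plain_binomial_glm(self, fit_panel):
        """With variance components pinned at zero the fit is an ordinary GLM."""
        sm = pytest.importorskip("statsmodels.api")
        _, panel = fit_panel
        model = MaskMandateGLMM.from_panel(panel)
        mine = model.fit(fix_var_components={"county": 0.0, "state": 0.0, "week": 0.0})
        glm = sm.GLM(
            np.column_stack([model.y, model.n - model.y]),
            model.X,
            family=sm.families.Binomial(),
        ).fit()
        assert np.abs(mine.params.values - glm.params).max() < 1e-4
        assert mine.llf == pytest.approx(glm.llf, abs=1e-6)
        assert np.abs(mine.bse.values - glm.bse).max() < 1e-6

    def test_zero_variance_generator_matches_glm_within_2se(self):
        params = GeneratorParams(
            n_counties=80, n_states=10, n_weeks=10, users_per_county_week=800,
            sigma2_county=0.0, sigma2_state=0.0, sigma2_week=0.0, seed=37,
        )
        panel = simulate_panel(params)
        model = MaskMandateGLMM.from_panel(panel)
        mixed = model.fit()
        plain = model.fit(fix_var_components={"county": 0.0, "state": 0.0, "week": 0.0})
        assert np.all(
            np.abs(mixed.params.values - plain.params.values) <= 2 * plain.bse.values
        )

    def test_duplicating_rows_leaves_glm_estimates_unchanged(self, fit_panel):
        _, panel = fit_panel
        doubled = pd.concat([panel, panel], ignore_index=True)
        zero = {"county": 0.0, "state": 0.0, "week": 0.0}
        a = MaskMandateGLMM.from_panel(panel).fit(fix_var_components=zero)
        b = MaskMandateGLMM.from_panel(doubled).fit(fix_var_components=zero)
        assert np.abs(a.params.values - b.params.values).max() < 1e-6
        assert b.llf == pytest.approx(2 * a.llf, rel=1e-9)

    def test_matches_lme4_reference_fit(self, fit_panel, tmp_path):
        """Independent oracle: lme4::glmer on the same panel."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; the lme4 cross-check cannot run")
        _, panel = fit_panel
        res = MaskMandateGLMM.from_panel(panel).fit()

        csv = tmp_path / "panel.csv"
        panel.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            f"""
            suppressMessages({{library(lme4); library(jsonlite)}})
            d <- read.csv("{csv}")
            d$mand <- as.integer(d$mandate_active == "True" | d$mandate_active == "TRUE")
            m <- glmer(cbind(n_mask_users, n_image_users - n_mask_users) ~
                mand * gop_vote_2016 + deaths_per_10k_lag + urban_pct + density +
                covid_news + retail_per_100 + week_counter +
                (1 | fips) + (1 | state) + (1 | week_index),
                data = d, family = binomial)
            vc <- as.data.frame(VarCorr(m))
            cat(toJSON(list(fixef = as.list(fixef(m)),
                            vc = setNames(as.list(vc$vcov), vc$grp),
                            llf = as.numeric(logLik(m))), auto_unbox = TRUE))
            """
        )
        out = subprocess.run(
            ["Rscript", str(rscript)], capture_output=True, text=True, check=True
        )
        ref = json.loads(out.stdout)
        name_map = {
            "intercept": "(Intercept)", "mandate": "mand", "gop": "gop_vote_2016",
            "mandate_gop": "mand:gop_vote_2016", "deaths": "deaths_per_10k_lag",
            "urban": "urban_pct", "density": "density", "news": "covid_news",
            "retail": "retail_per_100", "week": "week_counter",
        }
        for mine, theirs in name_map.items():
            tol = 0.05 * res.bse[mine] + 1e-4
            assert res.params[mine] == pytest.approx(ref["fixef"][theirs], abs=tol), mine
        vc_map = {"county": "fips", "state": "state", "week": "week_index"}
        for mine, theirs in vc_map.items():
            assert res.var_components[mine] == pytest.approx(
                ref["vc"][theirs], rel=0.2, abs=5e-3
            ), mine
        assert res.llf == pytest.approx(ref["llf"], abs=6.0)

    def test_nonconvergence_is_flagged_not_silent(self, fit_panel):
        _, panel = fit_panel
        res = MaskMandateGLMM.from_panel(panel).fit(maxiter=1)
        assert not res.converged

    def test_summary_mentions_all_terms(self, fit_panel):
        _, panel = fit_panel
        res = MaskMandateGLMM.from_panel(panel).fit()
        text = res.summary()
        for term in ("mandate_gop", "county", "AIC"):
            assert term in text


class TestEffectTranslation:
    @pytest.mark.parametrize(
        "coef, delta, expected",
        [(0.004, 25.0, 10.5), (-0.006, 12.8, -7.4), (0.0, 123.0, 0.0)],
    )
    def test_printed_percent_changes(self, coef, delta, expected):
        assert round(effect_per_sd(coef, delta), 1) == expected

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(-0.05, 0.05), st.floats(0.0, 30.0), st.floats(0.0, 30.0)
    )
    def test_exp_additivity(self, beta, d1, d2):
        combined = effect_per_sd(beta, d1 + d2)
        compounded = 100.0 * (
            (1 + effect_per_sd(beta, d1) / 100) * (1 + effect_per_sd(beta, d2) / 100) - 1
        )
        assert combined == pytest.approx(compounded, rel=1e-9, abs=1e-9)


@pytest.fixture(scope="module")
def fitted(fit_panel):
    _, panel = fit_panel
    return MaskMandateGLMM.from_panel(panel).fit()


class TestMarginalEffects:

    def test_positive_interaction_gives_increasing_effect(self, fitted):
        assert fitted.params["mandate_gop"] > 0
        curve = marginal_effect_curve(fitted, np.arange(25, 86, 5.0))
        assert (np.diff(curve.effect) > 0).all()
        assert ((curve.ci_low <= curve.effect) & (curve.effect <= curve.ci_high)).all()

    def test_zero_mandate_terms_give_flat_zero_curve(self, fitted):
        params = fitted.params.copy()
        params["mandate"] = 0.0
        params["mandate_gop"] = 0.0
        neutered = replace(fitted, params=params)
        curve = marginal_effect_curve(neutered, np.arange(25, 86, 10.0))
        assert np.allclose(curve.effect, 0.0)

    def test_main_effects_model_rejected(self, fit_panel):
        _, panel = fit_panel
        res = MaskMandateGLMM.from_panel(panel, interaction=False).fit()
        with pytest.raises(ValueError, match="interaction"):
            marginal_effect_curve(res, [40.0, 60.0])

    def test_delta_band_matches_sampling_oracle(self, fitted):
        """Delta-method CI vs simulating coefficient draws from the fitted
        normal approximation (2000 draws) at one grid point."""
        g = 55.0
        curve = marginal_effect_curve(fitted, [g])
        rng = np.random.default_rng(8)
        draws = rng.multivariate_normal(
            fitted.params.values, fitted.cov_beta.values, size=2000
        )
        names = list(fitted.params.index)
        means = fitted.model.X.mean(axis=0)
        x0, x1 = means.copy(), means.copy()
        x0[names.index("mandate")] = 0.0
        x0[names.index("mandate_gop")] = 0.0
        x1[names.index("mandate")] = 1.0
        x0[names.index("gop")] = x1[names.index("gop")] = g
        x1[names.index("mandate_gop")] = g
        effects = expit(draws @ x1) - expit(draws @ x0)
        sim_width = np.quantile(effects, 0.975) - np.quantile(effects, 0.025)
        delta_width = curve.ci_high[0] - curve.ci_low[0]
        assert delta_width == pytest.approx(sim_width, rel=0.2)


class TestComparison:
    def test_identical_fits_zero_aic_difference(self, fit_panel):
        _, panel = fit_panel
        res = MaskMandateGLMM.from_panel(panel).fit()
        table = compare_models({"a": res, "b": res})
        assert table.loc["a", "aic"] == table.loc["b", "aic"]

    def test_aic_identity(self, fit_panel):
        _, panel = fit_panel
        res = MaskMandateGLMM.from_panel(panel).fit()
        assert res.aic == pytest.approx(2 * res.k_params - 2 * res.llf)
        assert res.bic == pytest.approx(res.k_params * np.log(res.nobs) - 2 * res.llf)

    def test_differing_nobs_rejected(self, fit_panel, small_panel):
        _, panel = fit_panel
        a = MaskMandateGLMM.from_panel(panel).fit()
        b = MaskMandateGLMM.from_panel(small_panel).fit()
        with pytest.raises(ValueError, match="identical data"):
            compare_models({"a": a, "b": b})

    def test_interaction_generator_prefers_interaction_model(self):
        """When data are generated with the interaction, AIC should pick it
        in nearly every replicate at this effect size."""
        params = GeneratorParams(
            n_counties=60, n_states=12, n_weeks=22, users_per_county_week=2000, seed=0
        )
        wins = 0
        n_reps = 10
        rng = np.random.default_rng(55)
        for s in rng.integers(0, 2**31 - 1, n_reps):
            panel = simulate_panel(replace(params, seed=int(s)))
            fits = {
                "interaction": MaskMandateGLMM.from_panel(panel, interaction=True).fit(),
                "main": MaskMandateGLMM.from_panel(panel, interaction=False).fit(),
            }
            table = compare_models(fits)
            wins += bool(table.loc["interaction", "preferred"])
        assert wins >= 9


class TestRecovery:
    SMALL = GeneratorParams(
        n_counties=40, n_states=8, n_weeks=8, users_per_county_week=600,
        min_users_per_county_week=0,
    )

    def test_report_structure_and_reproducibility(self):
        a = recovery_study(self.SMALL, n_replicates=4, seed=5)
        b = recovery_study(self.SMALL, n_replicates=4, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.n_nonconverged == 0
        assert set(a.table.columns) == {
            "true", "mean_estimate", "bias", "empirical_se", "mean_model_se", "coverage",
        }
        assert list(a.table.index) == list(a.estimates.columns)

    def test_estimates_track_truth_loosely_at_small_scale(self):
        rep = recovery_study(self.SMALL, n_replicates=6, seed=19)
        mc_se = rep.table["empirical_se"] / np.sqrt(6)
        assert (rep.table["bias"].abs() <= 4 * mc_se + 1e-4).all()

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            recovery_study(self.SMALL, n_replicates=1, seed=1)
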