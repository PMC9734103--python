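"""Generator contracts: determinism, structure, and statistical calibration."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from masktrends.detection_eval import metrics_at
from masktrends.synthetic_data import (
    DEFAULT_BETAS,
    GeneratorParams,
    ScoreParams,
    latent_logit,
    make_gazetteer,
    make_mandate_schedule,
    national_latent_series,
    simulate_latent_prevalence,
    simulate_panel,
    simulate_scored_images,
    simulate_survey,
    simulate_tweets,
)


class TestGazetteer:
    def test_cardinalities_forced_by_parameters(self):
        params = GeneratorParams(n_counties=10, n_states=2, seed=7)
        counties, overlaps = make_gazetteer(params)
        assert len(counties) == 10
        assert counties["fips"].is_unique
        assert set(counties["state"]).issubset(set(counties["state"])) and counties[
            "state"
        ].nunique() == 2

    def test_seeded_determinism_byte_identical(self):
        params = GeneratorParams(n_counties=15, n_states=3, seed=11)
        a = make_gazetteer(params)
        b = make_gazetteer(params)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_no_multi_county_cities_when_fraction_zero(self):
        params = GeneratorParams(n_counties=30, n_states=3, multi_county_city_frac=0.0, seed=2)
        _, overlaps = make_gazetteer(params)
        assert (overlaps["pop_share"] == 1.0).all()

    def test_city_shares_sum_to_one(self):
        params = GeneratorParams(n_counties=40, n_states=4, multi_county_city_frac=0.5, seed=3)
        _, overlaps = make_gazetteer(params)
        sums = overlaps.groupby("city_id")["pop_share"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            GeneratorParams(n_counties=3, n_states=5)


class TestMandateSchedule:
    def test_full_adoption_from_week_one(self):
        params = GeneratorParams(
            n_counties=12, n_states=3, adoption_intercept=50.0, adoption_gop_slope=0.0,
            state_adoption_prob=0.0, seed=5,
        )
        counties, _ = make_gazetteer(params)
        sched = make_mandate_schedule(counties, params)
        assert set(sched["fips"]) == set(counties["fips"])

    def test_zero_adoption_gives_empty_schedule(self):
        params = GeneratorParams(
            n_counties=12, n_states=3, adoption_intercept=-50.0, adoption_gop_slope=0.0,
            state_adoption_prob=0.0, seed=5,
        )
        counties, _ = make_gazetteer(params)
        assert make_mandate_schedule(counties, params).empty

    def test_schedule_reproducible(self, small_params, small_world):
        counties, _, schedule = small_world
        again = make_mandate_schedule(counties, small_params)
        pd.testing.assert_frame_equal(schedule, again)


class TestLatentPrevalence:
    def test_inverse_logit_of_zero_linear_predictor(self):
        params = GeneratorParams(
            n_counties=8, n_states=2, n_weeks=4,
            betas={k: 0.0 for k in DEFAULT_BETAS},
            sigma2_county=0.0, sigma2_state=0.0, sigma2_week=0.0, seed=1,
        )
        counties, _ = make_gazetteer(params)
        sched = make_mandate_schedule(counties, params)
        panel = simulate_latent_prevalence(counties, sched, params)
        assert np.allclose(panel["p"], 0.5)

    def test_one_cell_matches_hand_computed_inverse_logit(self):
        """Independent recomputation of the logit-linear model for one cell."""
        row = pd.DataFrame(
            {
                "mandate_active": [True],
                "gop_vote_2016": [54.4],
                "deaths_per_10k_lag": [0.3],
                "urban_pct": [50.0],
                "density": [500.0],
                "covid_news": [4.0],
                "retail_per_100": [2.5],
                "week_counter": [11],
            }
        )
        b = DEFAULT_BETAS
        by_hand = (
            b["intercept"] + b["mandate"] + b["gop"] * 54.4 + b["mandate_gop"] * 54.4
            + b["deaths"] * 0.3 + b["urban"] * 50.0 + b["density"] * 500.0
            + b["news"] * 4.0 + b["retail"] * 2.5 + b["week"] * 11
        )
        assert expit(latent_logit(row, b))[0] == pytest.approx(1 / (1 + np.exp(-by_hand)))

    def test_county_intercept_variance_recovered_at_scale(self):
        """Sample variance of county intercepts ≈ configured variance (10%)."""
        params = GeneratorParams(
            n_counties=10_000, n_states=10, n_weeks=2,
            sigma2_county=0.037, sigma2_state=0.0, sigma2_week=0.0, seed=17,
        )
        counties, _ = make_gazetteer(params)
        sched = make_mandate_schedule(counties, params)
        panel = simulate_latent_prevalence(counties, sched, params)
        draws = panel.groupby("fips")["u_county"].first()
        assert np.var(draws, ddof=1) == pytest.approx(0.037, rel=0.10)

    def test_nonfinite_covariate_raises(self, small_params, small_world):
        counties, _, schedule = small_world
        bad = counties.copy()
        bad.loc[0, "gop_vote_2016"] = np.inf
        with pytest.raises(FloatingPointError):
            simulate_latent_prevalence(bad, schedule, small_params)


class TestPanel:
    def test_conservation_mask_users_bounded_by_image_users(self, small_panel):
        assert (small_panel["n_mask_users"] <= small_panel["n_image_users"]).all()

    def test_panel_deterministic(self, small_params, small_panel):
        pd.testing.assert_frame_equal(small_panel, simulate_panel(small_params))

    def test_default_scale_keeps_eligibility_floor(self):
        params = GeneratorParams(seed=23)
        panel = simulate_panel(params)
        assert panel["n_image_users"].min() >= 519
        assert len(panel) == 300 * 22


class TestTweetStream:
    def test_everyone_masks_when_probability_one(self, small_params, small_world):
        counties, overlaps, schedule = small_world
        latent = simulate_latent_prevalence(counties, schedule, small_params)
        latent = latent.assign(p=1.0)
        stream = simulate_tweets(counties, overlaps, latent, small_params)
        images = stream.loc[stream["has_image"].astype(bool)]
        by_user = images.groupby("user_id")["true_label"].max()
        assert (by_user == 1).all()

    def test_city_only_levels_carry_city_id(self, small_params, small_world):
        counties, overlaps, schedule = small_world
        params = replace(
            small_params,
            level_probs={"country": 0, "state": 0, "city": 1.0, "neighborhood": 0, "poi": 0},
        )
        latent = simulate_latent_prevalence(counties, schedule, params)
        stream = simulate_tweets(counties, overlaps, latent, params)
        assert (stream["geotag_level"] == "city").all()
        assert stream["city_id"].notna().all()

    def test_score_distribution_matches_threshold_operating_point(self):
        """At threshold 0.9 the calibrated scores give precision ≈ 0.93, recall ≈ 0.77."""
        images = simulate_scored_images(100_000, GeneratorParams(seed=29))
        row = metrics_at(images["score"], images["true_label"], 0.9)
        assert row.precision == pytest.approx(0.93, abs=0.05)
        assert row.recall == pytest.approx(0.77, abs=0.05)

    def test_bbox_well_formed(self, small_stream):
        assert (small_stream["bbox_w"] <= small_stream["bbox_e"]).all()
        assert (small_stream["bbox_s"] <= small_stream["bbox_n"]).all()


class TestSurvey:
    def test_noise_free_survey_is_affine_in_latent(self, small_panel, small_params):
        latent = national_latent_series(small_panel)
        params = replace(small_params, survey_noise_sd=0.0)
        survey = simulate_survey(latent, params)
        expected = params.survey_intercept + params.survey_slope * 100.0 * latent.values
        assert np.allclose(survey["pct_mask"], np.clip(expected, 0, 100))
        r = np.corrcoef(survey["pct_mask"], latent.values)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_moderate_noise_keeps_correlation_high(self, small_panel, small_params):
        """r > 0.6 in at least 95% of replicates at noise sd = 10% of range."""
        latent = national_latent_series(small_panel)
        scale = small_params.survey_slope * 100.0
        rng_range = scale * (latent.max() - latent.min())
        params = replace(small_params, survey_noise_sd=0.1 * rng_range)
        wins = 0
        for rep_seed in range(200):
            rng = np.random.default_rng(1000 + rep_seed)
            survey = simulate_survey(latent, params, rng=rng)
            r = np.corrcoef(survey["pct_mask"], latent.values)[0, 1]
            wins += r > 0.6
        assert wins >= 190
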