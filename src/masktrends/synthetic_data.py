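"""Synthetic inputs for the mask-wearing surveillance pipeline.

Generates every upstream artifact the pipeline consumes — a county
gazetteer, a city-to-county population-share table, a mandate schedule, a
geotagged image-tweet stream with classifier scores, and a weekly national
survey series — with the statistical structure the downstream analysis
assumes:

* county-week mask-posting prevalence follows a logit-linear model in
  mandate exposure, county GOP vote share, their interaction, and
  epidemiological/media/mobility covariates, plus independent Gaussian
  random intercepts for county, state, and week;
* classifier scores for mask / non-mask images follow two Beta
  distributions whose defaults were calibrated by grid search so that
  thresholding at 0.9 yields precision ≈ 0.93 and recall ≈ 0.77 at an
  image-level positive rate of 1.1%;
* the survey series is an affine transform of latent national prevalence
  plus Gaussian noise.

All randomness flows from a single root seed through named substreams, so
every output is byte-identical across reruns with the same parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .temporal_mandate import build_weeks, exposure_table

__all__ = [
    "GEOTAG_LEVELS",
    "DEFAULT_BETAS",
    "ScoreParams",
    "GeneratorParams",
    "substreams",
    "make_gazetteer",
    "make_mandate_schedule",
    "simulate_covariates",
    "latent_logit",
    "simulate_latent_prevalence",
    "simulate_panel",
    "simulate_tweets",
    "simulate_scored_images",
    "simulate_survey",
    "generate_all",
    "load_params",
]

GEOTAG_LEVELS = ("country", "state", "city", "neighborhood", "poi")

#: Fixed-effect defaults: the interaction-model column of the county-week
#: panel analysis (logit scale, covariates on their raw reporting units).
DEFAULT_BETAS: dict[str, float] = {
    "intercept": -5.065,
    "mandate": -0.055,
    "gop": -0.006,
    "mandate_gop": 0.003,
    "deaths": 0.011,
    "urban": 0.004,
    "density": 0.000,
    "news": 0.064,
    "retail": 0.008,
    "week": 0.029,
}

_STREAM_NAMES = ("gazetteer", "schedule", "covariates", "effects", "tweets", "survey", "images")


@dataclass(frozen=True)
class ScoreParams:
    """Beta shape parameters for classifier scores, one pair per true class.

    Defaults were chosen by grid search so that the implied confusion
    metrics at decision threshold 0.9 and positive rate 0.011 land on
    precision ≈ 0.93, recall ≈ 0.77.
    """

    pos_a: float = 0.20
    pos_b: float = 0.04
    neg_a: float = 0.03
    neg_b: float = 1.50

    @classmethod
    def perfect(cls) -> "ScoreParams":
        """Degenerate scores: positives score 1, negatives 0 (classifier noise off)."""
        return cls(pos_a=np.inf, pos_b=np.inf, neg_a=np.inf, neg_b=np.inf)

    @property
    def is_perfect(self) -> bool:
        return not np.isfinite(self.pos_a)

    def draw(self, labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        labels = np.asarray(labels)
        if self.is_perfect:
            return labels.astype(float)
        scores = rng.beta(self.neg_a, self.neg_b, size=labels.shape)
        pos = labels == 1
        scores[pos] = rng.beta(self.pos_a, self.pos_b, size=int(pos.sum()))
        return scores


@dataclass
class GeneratorParams:
    """Full parameterization of the synthetic study.

    Scale defaults mirror the study conditions of the county-week panel
    analysis: 300 counties in 45 states over 22 Monday-aligned weeks, with
    every panel county having at least 519 image-posting users per week
    (the per-county sample-size floor from the power analysis).
    """

    n_counties: int = 300
    n_states: int = 45
    n_weeks: int = 22
    start_date: date = date(2020, 3, 2)
    # logit-scale fixed effects of the prevalence model
    betas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETAS))
    # random-intercept variances
    sigma2_county: float = 0.037
    sigma2_state: float = 0.014
    sigma2_week: float = 0.027
    # tweet-stream scale
    users_per_county_week: float = 650.0
    min_users_per_county_week: int = 519
    population_sdlog: float = 0.20
    extra_tweets_per_user: float = 0.5  # textless tweets per image-posting user
    level_probs: dict[str, float] = field(
        default_factory=lambda: {
            "country": 0.04,
            "state": 0.03,
            "city": 0.55,
            "neighborhood": 0.25,
            "poi": 0.13,
        }
    )
    multi_county_city_frac: float = 0.14
    # classifier emulation
    pos_rate: float = 0.011
    score_params: ScoreParams = field(default_factory=ScoreParams)
    # covariate ranges (95% intervals of the all-counties summary table)
    gop_range: tuple[float, float] = (23.7, 85.1)
    # mandate adoption: P(adopt) = logistic(intercept + slope * (gop - 50))
    adoption_intercept: float = 0.5
    adoption_gop_slope: float = -0.04
    state_adoption_prob: float = 0.30
    # survey emulation: pct = intercept + slope * (100 * latent proportion) + noise
    survey_intercept: float = 10.0
    survey_slope: float = 35.0
    survey_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.n_counties >= self.n_states >= 1):
            raise ValueError("need n_counties >= n_states >= 1")
        if self.n_weeks < 2:
            raise ValueError("n_weeks must be >= 2")
        for name in ("sigma2_county", "sigma2_state", "sigma2_week"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0 < self.pos_rate < 1):
            raise ValueError("pos_rate must be in (0, 1)")
        if self.survey_noise_sd < 0:
            raise ValueError("survey_noise_sd must be nonnegative")
        total = sum(self.level_probs.get(k, 0.0) for k in GEOTAG_LEVELS)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("level_probs must sum to 1 over the five geotag levels")

    def sigma2(self) -> dict[str, float]:
        return {
            "county": self.sigma2_county,
            "state": self.sigma2_state,
            "week": self.sigma2_week,
        }


def substreams(seed: int) -> dict[str, np.random.Generator]:
    """Named, independent random substreams derived from one root seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAM_NAMES))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAM_NAMES, children)}


# ---------------------------------------------------------------------------
# geography


def make_gazetteer(params: GeneratorParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic county gazetteer and city→county population-share table.

    FIPS codes are arbitrary 5-character zero-padded labels; no real US
    geography is emulated. Each county hosts exactly one city; a
    configurable fraction of cities spill over into a second county, with
    the home county always holding the majority population share (so
    majority-share resolution maps a city back to its home county).
    """
    rng = substreams(params.seed)["gazetteer"]
    n, s = params.n_counties, params.n_states
    fips = np.array([f"{i + 1:05d}" for i in range(n)])
    # every state gets at least one county; remainder assigned at random
    state_codes = np.array(
        [f"{chr(65 + i // 26)}{chr(65 + i % 26)}" for i in range(s)]
    )
    state_idx = np.concatenate([np.arange(s), rng.integers(0, s, size=n - s)])
    rng.shuffle(state_idx)
    lo, hi = params.gop_range
    counties = pd.DataFrame(
        {
            "fips": fips,
            "state": state_codes[state_idx],
            "population": np.round(
                1e5 * rng.lognormal(mean=0.0, sigma=params.population_sdlog, size=n)
            ).astype(int),
            "urban_pct": rng.uniform(0.0, 100.0, size=n),
            "density": rng.lognormal(mean=4.76, sigma=1.59, size=n),
            "gop_vote_2016": rng.uniform(lo, hi, size=n),
        }
    )

    rows = []
    spill = rng.random(n) < params.multi_county_city_frac
    for i in range(n):
        city_id = f"C{i + 1:05d}"
        if spill[i] and n > 1:
            j = int(rng.integers(0, n - 1))
            j = j + 1 if j >= i else j  # a different county
            share = float(rng.uniform(0.55, 0.90))
            rows.append((city_id, fips[i], share))
            rows.append((city_id, fips[j], 1.0 - share))
        else:
            rows.append((city_id, fips[i], 1.0))
    overlaps = pd.DataFrame(rows, columns=["city_id", "fips", "pop_share"])
    return counties, overlaps


def make_mandate_schedule(
    counties: pd.DataFrame, params: GeneratorParams
) -> pd.DataFrame:
    """Mandate records with adoption probability logistic in GOP vote share.

    County mandates: each county adopts with probability
    ``logistic(adoption_intercept + adoption_gop_slope * (gop - 50))`` and,
    if it adopts, its effective date falls uniformly in weeks 2..n_weeks.
    A subset of states additionally issue state-wide mandates (recorded
    against one member county with level="state"). Some counties never
    adopt. No repeals.
    """
    rng = substreams(params.seed)["schedule"]
    n_days = 7 * params.n_weeks
    start = params.start_date

    gop = counties["gop_vote_2016"].values
    p_adopt = 1.0 / (1.0 + np.exp(-(params.adoption_intercept + params.adoption_gop_slope * (gop - 50.0))))
    adopts = rng.random(len(counties)) < p_adopt
    offsets = rng.integers(7, n_days, size=len(counties))
    rows = [
        (f, start + timedelta(days=int(o)), "county")
        for f, a, o in zip(counties["fips"], adopts, offsets)
        if a
    ]

    for state, group in counties.groupby("state"):
        if rng.random() < params.state_adoption_prob:
            o = int(rng.integers(7, n_days))
            rows.append((group["fips"].iloc[0], start + timedelta(days=o), "state"))

    return pd.DataFrame(rows, columns=["fips", "effective_date", "level"])


# ---------------------------------------------------------------------------
# covariates and the latent prevalence surface


def _ar1(rng: np.random.Generator, n: int, size: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) paths, shape (size, n), marginal N(0, sd^2)."""
    x = np.empty((size, n))
    x[:, 0] = rng.normal(0.0, sd, size=size)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    for t in range(1, n):
        x[:, t] = phi * x[:, t - 1] + rng.normal(0.0, innov_sd, size=size)
    return x


def simulate_covariates(
    counties: pd.DataFrame, params: GeneratorParams, rng: np.random.Generator
) -> pd.DataFrame:
    """County-week time-varying covariates plus the national news series.

    Deaths per 10k residents (lagged one week downstream), retail visits
    per hundred residents, and the national COVID-news intensity are
    nonnegative autocorrelated series whose stationary 95% ranges
    approximate the published all-county summary intervals.
    """
    n, w = len(counties), params.n_weeks
    deaths = np.abs(_ar1(rng, w, n, phi=0.6, sd=0.40))
    retail = np.exp(np.log(1.8) + _ar1(rng, w, n, phi=0.7, sd=0.50))
    news = np.exp(np.log(3.0) + _ar1(rng, w, 1, phi=0.7, sd=0.70))[0]

    weeks = np.arange(1, w + 1)
    out = pd.DataFrame(
        {
            "fips": np.repeat(counties["fips"].values, w),
            "week_index": np.tile(weeks, n),
            "deaths_per_10k": deaths.ravel(),
            "retail_per_100": retail.ravel(),
        }
    )
    # lag deaths one week within county; week 1 lag defined as 0
    lagged = np.concatenate([np.zeros((n, 1)), deaths[:, :-1]], axis=1)
    out["deaths_per_10k_lag"] = lagged.ravel()
    out["covid_news"] = np.tile(news, n)
    return out


def latent_logit(panel: pd.DataFrame, betas: Mapping[str, float]) -> np.ndarray:
    """Linear predictor of the prevalence model evaluated on panel columns."""
    m = panel["mandate_active"].astype(float).values
    gop = panel["gop_vote_2016"].values
    return (
        betas["intercept"]
        + betas["mandate"] * m
        + betas["gop"] * gop
        + betas.get("mandate_gop", 0.0) * m * gop
        + betas["deaths"] * panel["deaths_per_10k_lag"].values
        + betas["urban"] * panel["urban_pct"].values
        + betas["density"] * panel["density"].values
        + betas["news"] * panel["covid_news"].values
        + betas["retail"] * panel["retail_per_100"].values
        + betas["week"] * panel["week_counter"].values
    )


def simulate_latent_prevalence(
    counties: pd.DataFrame,
    schedule: pd.DataFrame,
    params: GeneratorParams,
    *,
    rng_covariates: np.random.Generator | None = None,
    rng_effects: np.random.Generator | None = None,
) -> pd.DataFrame:
    """County-week probability surface p_jt of posting a mask image.

    ``logit(p_jt)`` is the configured linear predictor plus independent
    Gaussian random intercepts for county, state, and week. Returns the
    long panel with covariates, the random-effect draws, ``eta``, and ``p``.
    """
    streams = substreams(params.seed)
    rng_cov = rng_covariates or streams["covariates"]
    rng_eff = rng_effects or streams["effects"]

    weeks = build_weeks(params.start_date, params.n_weeks)
    exposure = exposure_table(counties, weeks, schedule)
    cov = simulate_covariates(counties, params, rng_cov)

    panel = exposure.merge(cov, on=["fips", "week_index"], how="left").merge(
        counties[["fips", "state", "population", "gop_vote_2016", "urban_pct", "density"]],
        on="fips",
        how="left",
    )
    panel["week_counter"] = panel["week_index"]

    states = counties["state"].unique()
    u_county = dict(zip(counties["fips"], rng_eff.normal(0.0, np.sqrt(params.sigma2_county), len(counties))))
    u_state = dict(zip(states, rng_eff.normal(0.0, np.sqrt(params.sigma2_state), len(states))))
    u_week = dict(zip(range(1, params.n_weeks + 1), rng_eff.normal(0.0, np.sqrt(params.sigma2_week), params.n_weeks)))
    panel["u_county"] = panel["fips"].map(u_county)
    panel["u_state"] = panel["state"].map(u_state)
    panel["u_week"] = panel["week_index"].map(u_week)

    eta = latent_logit(panel, params.betas) + panel[["u_county", "u_state", "u_week"]].sum(axis=1).values
    if not np.all(np.isfinite(eta)):
        raise FloatingPointError("non-finite linear predictor in latent prevalence")
    panel["eta"] = eta
    panel["p"] = 1.0 / (1.0 + np.exp(-eta))
    return panel


def simulate_panel(params: GeneratorParams) -> pd.DataFrame:
    """Complete county-week panel with user counts, ready for model fitting.

    Draws ``n_image_users ~ Poisson(rate ∝ population)``, floored at the
    per-county eligibility minimum (emulating the populous-county screen of
    the study design), and ``n_mask_users ~ Binomial(n_image_users, p_jt)``.
    This bypasses the event stream: aggregating user-level Bernoulli draws
    gives exactly this Binomial, so the two routes agree in distribution.
    """
    counties, _ = make_gazetteer(params)
    schedule = make_mandate_schedule(counties, params)
    panel = simulate_latent_prevalence(counties, schedule, params)

    rng = substreams(params.seed)["tweets"]
    rates = params.users_per_county_week * (
        panel["population"].values / counties["population"].mean()
    )
    n_users = rng.poisson(rates)
    n_users = np.maximum(n_users, params.min_users_per_county_week)
    panel["n_image_users"] = n_users
    panel["n_mask_users"] = rng.binomial(n_users, panel["p"].values)
    return panel


# ---------------------------------------------------------------------------
# event stream


def _bbox(level: np.ndarray, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    half = np.select(
        [level == "country", level == "state", level == "city", level == "neighborhood"],
        [25.0, 3.0, 0.15, 0.01],
        default=0.0,  # poi: a point
    )
    return np.column_stack([lon - half, lat - half, lon + half, lat + half])


def simulate_tweets(
    counties: pd.DataFrame,
    overlaps: pd.DataFrame,
    panel: pd.DataFrame,
    params: GeneratorParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Geotagged tweet stream realizing a latent prevalence panel.

    Per county-week cell, ``Poisson(rate ∝ population)`` users each post one
    image tweet (a mask image with probability p_jt, else a non-mask image)
    plus a Poisson number of textless tweets. Geotag precision is drawn from
    ``level_probs``: city-level tweets reference the county's city (resolved
    downstream via population shares), neighborhood/POI tweets carry the
    county FIPS directly, and country/state tweets carry neither — the
    precision filter drops them. Classifier scores attach to image tweets
    only.
    """
    if rng is None:
        rng = substreams(params.seed)["tweets"]
    sp = params.score_params

    home_city = {f: f"C{int(f):05d}" for f in counties["fips"]}
    centroids = {
        f: (float(lon), float(lat))
        for f, lon, lat in zip(
            counties["fips"],
            rng.uniform(-120, -70, len(counties)),
            rng.uniform(25, 48, len(counties)),
        )
    }
    pop_mean = counties["population"].mean()
    pop = counties.set_index("fips")["population"]

    rates = params.users_per_county_week * panel["fips"].map(pop).values / pop_mean
    n_users = rng.poisson(rates)
    total = int(n_users.sum())

    cell_fips = np.repeat(panel["fips"].values, n_users)
    cell_week = np.repeat(panel["week_index"].values, n_users)
    cell_p = np.repeat(panel["p"].values, n_users)
    is_masker = rng.random(total) < cell_p

    user_id = np.array(
        [f"u{f}w{w}n{k}" for f, w, k in zip(cell_fips, cell_week, _within_cell_counter(n_users))]
    )

    frames = []
    # one image tweet per user
    label = is_masker.astype(int)
    score = sp.draw(label, rng)
    frames.append(
        _event_frame(cell_fips, cell_week, user_id, has_image=True, score=score, label=label)
    )
    # textless extras
    extra = rng.poisson(params.extra_tweets_per_user, size=total)
    rep = np.repeat(np.arange(total), extra)
    if len(rep):
        frames.append(
            _event_frame(
                cell_fips[rep], cell_week[rep], user_id[rep],
                has_image=False,
                score=np.full(len(rep), np.nan),
                label=np.full(len(rep), -1),
            )
        )
    events = pd.concat(frames, ignore_index=True)

    n = len(events)
    levels = np.array(GEOTAG_LEVELS)
    probs = np.array([params.level_probs[k] for k in GEOTAG_LEVELS])
    level = levels[rng.choice(len(levels), size=n, p=probs)]
    events["geotag_level"] = level

    lonlat = np.array([centroids[f] for f in events["county_of_origin"]])
    jitter = rng.normal(0.0, 0.05, size=(n, 2))
    box = _bbox(level, lonlat[:, 0] + jitter[:, 0], lonlat[:, 1] + jitter[:, 1])
    events[["bbox_w", "bbox_s", "bbox_e", "bbox_n"]] = box

    is_city = level == "city"
    is_subcity = np.isin(level, ("neighborhood", "poi"))
    events["city_id"] = pd.array(
        np.where(is_city, events["county_of_origin"].map(home_city), None), dtype="string"
    )
    events["fips"] = pd.array(
        np.where(is_subcity, events["county_of_origin"], None), dtype="string"
    )

    # timestamps uniform over the tweet's study week
    day = rng.integers(0, 7, size=n)
    sec = rng.integers(0, 86400, size=n)
    week_start = pd.Timestamp(params.start_date)
    ts = (
        week_start
        + pd.to_timedelta((events["week_index"].values - 1) * 7 + day, unit="D")
        + pd.to_timedelta(sec, unit="s")
    )
    events["timestamp"] = ts

    events["tweet_id"] = [f"t{i:09d}" for i in range(n)]
    events["true_label"] = events["true_label"].where(events["has_image"], other=pd.NA)
    cols = [
        "tweet_id", "user_id", "timestamp", "geotag_level",
        "bbox_w", "bbox_s", "bbox_e", "bbox_n", "city_id",
        "has_image", "score", "true_label", "fips", "county_of_origin", "week_index",
    ]
    return events[cols]


def _within_cell_counter(n_users: np.ndarray) -> np.ndarray:
    out = np.arange(int(n_users.sum()))
    offsets = np.repeat(np.concatenate([[0], np.cumsum(n_users)[:-1]]), n_users)
    return out - offsets


def _event_frame(fips, week, user, *, has_image, score, label) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "county_of_origin": fips,
            "week_index": week,
            "user_id": user,
            "has_image": has_image,
            "score": score,
            "true_label": label,
        }
    )


def simulate_scored_images(
    n_images: int, params: GeneratorParams, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """A standalone validation set of (true_label, score) pairs.

    Labels are Bernoulli(``pos_rate``); scores come from the class-specific
    Beta distributions. Emulates a held-out hand-annotated image set used
    to pick the decision threshold.
    """
    if rng is None:
        rng = substreams(params.seed)["images"]
    labels = (rng.random(n_images) < params.pos_rate).astype(int)
    scores = params.score_params.draw(labels, rng)
    return pd.DataFrame({"true_label": labels, "score": scores})


# ---------------------------------------------------------------------------
# survey


def national_latent_series(panel: pd.DataFrame) -> pd.Series:
    """Population-weighted national weekly latent prevalence (proportion)."""
    def _wmean(g: pd.DataFrame) -> float:
        return float(np.average(g["p"], weights=g["population"]))

    return panel.groupby("week_index").apply(_wmean, include_groups=False)


def simulate_survey(
    latent: pd.Series, params: GeneratorParams, rng: np.random.Generator | None = None,
    source: str = "synthetic-survey",
) -> pd.DataFrame:
    """Weekly survey series: affine in latent prevalence plus noise, clipped.

    ``pct_mask = intercept + slope * (100 * latent) + N(0, noise_sd)``,
    clipped to [0, 100]. ``latent`` is a proportion series indexed by
    week_index.
    """
    if rng is None:
        rng = substreams(params.seed)["survey"]
    vals = (
        params.survey_intercept
        + params.survey_slope * 100.0 * latent.values
        + rng.normal(0.0, params.survey_noise_sd, size=len(latent))
    )
    return pd.DataFrame(
        {
            "week_index": latent.index.values,
            "pct_mask": np.clip(vals, 0.0, 100.0),
            "source": source,
        }
    )


# ---------------------------------------------------------------------------
# I/O


def generate_all(params: GeneratorParams, outdir: str | Path) -> dict[str, Path]:
    """Generate and write every pipeline input CSV; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counties, overlaps = make_gazetteer(params)
    schedule = make_mandate_schedule(counties, params)
    panel = simulate_latent_prevalence(counties, schedule, params)
    tweets = simulate_tweets(counties, overlaps, panel, params)
    survey = simulate_survey(national_latent_series(panel), params)

    files = {}
    files["gazetteer"] = outdir / "gazetteer.csv"
    counties.to_csv(files["gazetteer"], index=False)
    files["city_overlap"] = outdir / "city_overlap.csv"
    overlaps.to_csv(files["city_overlap"], index=False)
    files["mandates"] = outdir / "mandates.csv"
    schedule.assign(effective_date=pd.to_datetime(schedule["effective_date"]).dt.date).to_csv(
        files["mandates"], index=False
    )
    files["covariates"] = outdir / "covariates.csv"
    panel[
        ["fips", "week_index", "mandate_active", "deaths_per_10k", "deaths_per_10k_lag",
         "retail_per_100", "covid_news", "week_counter"]
    ].to_csv(files["covariates"], index=False)
    files["tweets"] = outdir / "tweets.csv"
    out = tweets.drop(columns=["county_of_origin", "week_index"]).copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(files["tweets"], index=False)
    files["survey"] = outdir / "survey.csv"
    survey.to_csv(files["survey"], index=False)
    return files


def load_params(path: str | Path) -> GeneratorParams:
    """Read GeneratorParams from a YAML or JSON config file."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    return params_from_dict(raw or {})


def params_from_dict(raw: Mapping) -> GeneratorParams:
    kwargs = dict(raw)
    if "start_date" in kwargs and isinstance(kwargs["start_date"], str):
        kwargs["start_date"] = date.fromisoformat(kwargs["start_date"])
    if "score_params" in kwargs and isinstance(kwargs["score_params"], Mapping):
        kwargs["score_params"] = ScoreParams(**kwargs["score_params"])
    if "gop_range" in kwargs:
        kwargs["gop_range"] = tuple(kwargs["gop_range"])
    return GeneratorParams(**kwargs)


def params_to_dict(params: GeneratorParams) -> dict:
    d = asdict(params)
    d["start_date"] = params.start_date.isoformat()
    d["gop_range"] = list(params.gop_range)
    return d
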