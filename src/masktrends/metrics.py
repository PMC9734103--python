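"""The mask-wearing statistic and its validation-series operations.

The core measure, at county-week or national-week resolution, is the
fraction of users who posted at least one image classified as mask-wearing
among users who posted at least one image of any kind that week.
Deduplication is by user within a county-week: a user's tenth image that
week changes nothing. A user who geotags in two counties in one week
contributes to both counties' denominators; the national denominator is
the sum of county denominators.

County-weeks with no image-posting users are missing, not zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .temporal_mandate import StudyWeek

__all__ = [
    "assign_weeks",
    "user_week_rollup",
    "county_week_metric",
    "national_series",
    "first_difference",
    "pearson_correlation",
    "build_panel",
]


def assign_weeks(events: pd.DataFrame, weeks: list[StudyWeek]) -> pd.DataFrame:
    """Attach a ``week_index`` from timestamps; drops out-of-window events."""
    start = pd.Timestamp(weeks[0].monday)
    end = pd.Timestamp(weeks[-1].sunday) + pd.Timedelta(days=1)
    # timestamps are civil UTC; strip any tz marker to compare with civil dates
    ts = pd.to_datetime(events["timestamp"], utc=True).dt.tz_localize(None)
    inside = (ts >= start) & (ts < end)
    out = events.loc[inside].copy()
    out["week_index"] = ((ts[inside] - start).dt.days // 7) + 1
    return out


def user_week_rollup(events: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Per (user, county, week): did they post any image / any mask image.

    ``posted_mask`` is true iff any of the user's images that week in that
    county scores at or above the detection threshold. Users with no image
    events drop out of the rollup entirely (they are not in any
    denominator). Duplicate events are harmless: the flags are ORs.
    """
    ev = events.copy()
    ev["is_image"] = ev["has_image"].astype(bool)
    ev["is_mask"] = ev["is_image"] & (ev["score"].astype(float) >= threshold)
    grouped = (
        ev.groupby(["user_id", "fips", "week_index"], sort=False)[["is_image", "is_mask"]]
        .any()
        .reset_index()
        .rename(columns={"is_image": "posted_image", "is_mask": "posted_mask"})
    )
    return grouped.loc[grouped["posted_image"]].reset_index(drop=True)


def county_week_metric(rollup: pd.DataFrame) -> pd.DataFrame:
    """Counts of image-posting and mask-posting users per county-week.

    ``proportion`` = n_mask_users / n_image_users; NaN (flagged via
    n_image_users == 0 being absent) only arises for county-weeks not in
    the rollup at all — callers reindexing over a full panel grid get NaN
    there, not 0.
    """
    agg = (
        rollup.groupby(["fips", "week_index"])
        .agg(
            n_image_users=("posted_image", "sum"),
            n_mask_users=("posted_mask", "sum"),
        )
        .reset_index()
    )
    agg["proportion"] = agg["n_mask_users"] / agg["n_image_users"]
    return agg


def national_series(rollup: pd.DataFrame) -> pd.DataFrame:
    """Weekly national proportion, pooled over counties (count-weighted)."""
    agg = (
        rollup.groupby("week_index")
        .agg(
            n_image_users=("posted_image", "sum"),
            n_mask_users=("posted_mask", "sum"),
        )
        .reset_index()
    )
    agg["proportion"] = agg["n_mask_users"] / agg["n_image_users"]
    return agg


def first_difference(series) -> np.ndarray:
    """d_t = x_{t+1} − x_t; length drops by one. Pre-whitening for trends."""
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("first_difference needs a series of length >= 2")
    if np.isnan(x).any():
        raise ValueError("first_difference requires no missing interior values")
    return np.diff(x)


def pearson_correlation(x, y) -> tuple[float, float, int]:
    """Pairwise-complete Pearson r with a two-sided t-test p-value.

    Returns (r, p, N) where N is the number of complete pairs. Raises on
    fewer than 3 complete pairs or zero variance in either series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, have {n}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: a series has zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def build_panel(
    county_metrics: pd.DataFrame,
    counties: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the county-week model panel from measured counts.

    Joins measured user counts onto static county attributes and the
    time-varying covariate table (which carries mandate exposure, lagged
    deaths, national news, retail visits, and the week counter). Rows with
    no image-posting users are absent — the missing-data convention — and
    the model-fitting layer excludes them.
    """
    panel = covariates.merge(
        counties[["fips", "state", "population", "gop_vote_2016", "urban_pct", "density"]],
        on="fips",
        how="left",
    ).merge(
        county_metrics[["fips", "week_index", "n_image_users", "n_mask_users", "proportion"]],
        on=["fips", "week_index"],
        how="left",
    )
    if "week_counter" not in panel.columns:
        panel["week_counter"] = panel["week_index"]
    return panel
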