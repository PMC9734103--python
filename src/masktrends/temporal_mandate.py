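"""Study-week calendar and county-week mandate exposure coding.

The unit of observation downstream is the county-week dyad on a
Monday–Sunday calendar. A county-week counts as "under a mandate" if any
mandate covering the county (its own, or one issued by its state) took
effect on or before the Thursday of that week — the midpoint rule that
avoids coding a week as exposed when the mandate covered only its tail.

Repeals are outside the data model: exposure, once switched on, stays on.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "StudyWeek",
    "build_weeks",
    "mandate_active",
    "exposure_table",
    "coverage_series",
]


@dataclass(frozen=True)
class StudyWeek:
    """One Monday–Sunday calendar week of the study window."""

    week_index: int  # 1-based
    monday: date
    sunday: date
    thursday: date

    def __post_init__(self) -> None:
        if self.sunday != self.monday + timedelta(days=6):
            raise ValueError("sunday must be monday + 6 days")
        if self.thursday != self.monday + timedelta(days=3):
            raise ValueError("thursday must be monday + 3 days")


def build_weeks(start_date: date, n_weeks: int) -> list[StudyWeek]:
    """Build ``n_weeks`` consecutive Monday-aligned study weeks.

    Parameters
    ----------
    start_date
        The Monday the first week begins on. Any other weekday raises
        ``ValueError``: partial weeks are not representable.
    n_weeks
        Number of consecutive weeks, at least 1.
    """
    if start_date.weekday() != 0:
        raise ValueError(f"start_date {start_date} is not a Monday")
    if n_weeks < 1:
        raise ValueError("n_weeks must be >= 1")
    weeks = []
    for i in range(n_weeks):
        monday = start_date + timedelta(weeks=i)
        weeks.append(
            StudyWeek(
                week_index=i + 1,
                monday=monday,
                sunday=monday + timedelta(days=6),
                thursday=monday + timedelta(days=3),
            )
        )
    return weeks


def _validate_mandates(mandates: pd.DataFrame) -> pd.DataFrame:
    required = {"fips", "effective_date", "level"}
    missing = required - set(mandates.columns)
    if missing:
        raise ValueError(f"mandate table missing columns: {sorted(missing)}")
    bad = set(mandates["level"]) - {"county", "state"}
    if bad:
        raise ValueError(f"unknown mandate levels: {sorted(bad)}")
    return mandates


def first_effective_date(
    counties: pd.DataFrame, mandates: pd.DataFrame
) -> pd.Series:
    """Earliest mandate date covering each county, or NaT if never mandated.

    County-level records apply to their own county; state-level records
    apply to every county whose ``state`` matches the state of the record's
    ``fips``. The union (earliest of the two) determines exposure.
    """
    mandates = _validate_mandates(mandates)
    state_of = counties.set_index("fips")["state"]
    unknown = set(mandates["fips"]) - set(state_of.index)
    if unknown:
        raise ValueError(f"mandate records reference unknown fips: {sorted(unknown)[:5]}")

    eff = pd.Series(pd.NaT, index=counties["fips"], dtype="datetime64[ns]", name="effective_date")
    dates = pd.to_datetime(mandates["effective_date"])

    county_rows = mandates["level"] == "county"
    if county_rows.any():
        first = dates[county_rows].groupby(mandates.loc[county_rows, "fips"]).min()
        eff.loc[first.index] = first

    state_rows = mandates["level"] == "state"
    if state_rows.any():
        by_state = (
            dates[state_rows]
            .groupby(mandates.loc[state_rows, "fips"].map(state_of))
            .min()
        )
        state_dates = counties["state"].map(by_state).values
        eff = pd.Series(
            np.fmin(eff.values, state_dates), index=eff.index, name="effective_date"
        )
    return eff


def mandate_active(
    fips: str,
    week: StudyWeek,
    mandates: pd.DataFrame,
    counties: pd.DataFrame,
) -> bool:
    """True iff a mandate covering ``fips`` started on or before the week's Thursday."""
    if fips not in set(counties["fips"]):
        raise ValueError(f"unknown fips: {fips}")
    eff = first_effective_date(counties, mandates).loc[fips]
    if pd.isna(eff):
        return False
    return eff.date() <= week.thursday


def exposure_table(
    counties: pd.DataFrame,
    weeks: list[StudyWeek],
    mandates: pd.DataFrame,
) -> pd.DataFrame:
    """Long county × week table with a boolean ``mandate_active`` column."""
    eff = first_effective_date(counties, mandates)
    thursdays = pd.to_datetime([w.thursday for w in weeks])
    active = eff.values[:, None] <= thursdays.values[None, :]
    out = pd.DataFrame(
        {
            "fips": np.repeat(counties["fips"].values, len(weeks)),
            "week_index": np.tile([w.week_index for w in weeks], len(counties)),
            "mandate_active": active.ravel(),
        }
    )
    return out


def coverage_series(
    counties: pd.DataFrame,
    weeks: list[StudyWeek],
    mandates: pd.DataFrame,
) -> pd.DataFrame:
    """Per-week share of counties, and of population, under a mandate."""
    exp = exposure_table(counties, weeks, mandates)
    pop = counties.set_index("fips")["population"]
    exp = exp.assign(population=exp["fips"].map(pop))
    grp = exp.groupby("week_index")
    county_share = grp["mandate_active"].mean()
    pop_share = grp.apply(
        lambda g: g.loc[g["mandate_active"], "population"].sum() / g["population"].sum(),
        include_groups=False,
    )
    return pd.DataFrame(
        {
            "week_index": county_share.index,
            "county_share": county_share.values,
            "population_share": pop_share.values,
        }
    )
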