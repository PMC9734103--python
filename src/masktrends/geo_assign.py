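"""Geotag precision filtering and tweet-to-county resolution.

Geotagged tweets carry a bounding box at one of five user-chosen precision
levels (country, state, city, neighborhood, point of interest). Boxes above
the city level are too coarse to localize a county and are dropped — with
an explicit report, never silently. City-level tweets name a city that may
span several counties; they resolve to the county covering the greatest
share of the city's population (ties broken by lexicographically smallest
FIPS). Neighborhood/POI tweets carry their county directly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .synthetic_data import GEOTAG_LEVELS

__all__ = [
    "DROPPED_LEVELS",
    "RETAINED_LEVELS",
    "DropReport",
    "AssignmentReport",
    "filter_by_level",
    "resolve_county",
    "assign_all",
]

DROPPED_LEVELS = frozenset({"country", "state"})
RETAINED_LEVELS = frozenset({"city", "neighborhood", "poi"})


class GeoAssignError(ValueError):
    """A tweet could not be validated or resolved to a county."""


@dataclass(frozen=True)
class DropReport:
    n_input: int
    n_retained: int
    n_dropped: int
    drop_fraction: float  # 0 for empty input

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class AssignmentReport:
    drop: DropReport
    n_city_level: int
    n_city_multi_county: int
    multi_county_share: float  # among city-level retained tweets

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drop"] = self.drop.to_dict()
        return d


def _check_levels(events: pd.DataFrame) -> None:
    known = set(GEOTAG_LEVELS)
    bad = ~events["geotag_level"].isin(known)
    if bad.any():
        offender = events.loc[bad].iloc[0]
        raise GeoAssignError(
            f"unknown geotag_level {offender['geotag_level']!r} "
            f"on tweet_id {offender.get('tweet_id', '<unknown>')!r}"
        )


def filter_by_level(events: pd.DataFrame) -> tuple[pd.DataFrame, DropReport]:
    """Drop tweets whose bounding box is above city precision.

    Returns the retained events and a count/fraction report of the drops.
    """
    _check_levels(events)
    keep = events["geotag_level"].isin(RETAINED_LEVELS)
    retained = events.loc[keep].copy()
    n = len(events)
    n_drop = int((~keep).sum())
    return retained, DropReport(
        n_input=n,
        n_retained=n - n_drop,
        n_dropped=n_drop,
        drop_fraction=(n_drop / n) if n else 0.0,
    )


def _city_resolution_map(overlaps: pd.DataFrame) -> pd.Series:
    """city_id -> FIPS of the county with the greatest population share.

    Ties in pop_share resolve to the lexicographically smallest FIPS.
    """
    ordered = overlaps.sort_values(
        ["city_id", "pop_share", "fips"], ascending=[True, False, True]
    )
    return ordered.groupby("city_id", sort=False)["fips"].first()


def resolve_county(event: pd.Series | dict, overlaps: pd.DataFrame) -> str:
    """Resolve a single retained tweet to its county FIPS."""
    level = event["geotag_level"]
    if level in DROPPED_LEVELS:
        raise GeoAssignError(f"cannot resolve a {level}-level tweet to a county")
    if level == "city":
        city = event.get("city_id") if isinstance(event, dict) else event["city_id"]
        cmap = _city_resolution_map(overlaps)
        if city not in cmap.index:
            raise GeoAssignError(f"city_id {city!r} absent from the overlap table")
        return str(cmap.loc[city])
    fips = event["fips"]
    if fips is None or (isinstance(fips, float) and np.isnan(fips)):
        raise GeoAssignError("sub-city tweet lacks a direct county FIPS")
    return str(fips)


def assign_all(
    events: pd.DataFrame, overlaps: pd.DataFrame
) -> tuple[pd.DataFrame, AssignmentReport]:
    """Filter by precision then resolve every retained tweet to one county.

    Idempotent: re-running on already-resolved output changes nothing.
    The report carries the drop counts and the share of city-level tweets
    whose city spans more than one county.
    """
    retained, drop = filter_by_level(events)

    cmap = _city_resolution_map(overlaps)
    multi_cities = set(
        overlaps.groupby("city_id")["fips"].nunique().loc[lambda s: s > 1].index
    )

    is_city = (retained["geotag_level"] == "city").values
    out = retained.copy()
    if is_city.any():
        cities = out.loc[is_city, "city_id"]
        missing = set(cities.dropna()) - set(cmap.index)
        if missing:
            raise GeoAssignError(
                f"city_id values absent from the overlap table: {sorted(missing)[:5]}"
            )
        out.loc[is_city, "fips"] = cities.map(cmap).values

    unresolved = out["fips"].isna()
    if unresolved.any():
        raise GeoAssignError(
            f"{int(unresolved.sum())} sub-city tweets lack a county FIPS "
            f"(first tweet_id: {out.loc[unresolved].iloc[0].get('tweet_id')!r})"
        )

    n_city = int(is_city.sum())
    n_multi = int(retained.loc[is_city, "city_id"].isin(multi_cities).sum())
    report = AssignmentReport(
        drop=drop,
        n_city_level=n_city,
        n_city_multi_county=n_multi,
        multi_county_share=(n_multi / n_city) if n_city else 0.0,
    )
    return out, report
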