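"""Power analysis, county eligibility, case-control sampling, odds ratios.

The per-county sample-size requirement comes from the two-proportion power
calculation with Cohen's arcsine effect size
``h = 2(arcsin√p_alt − arcsin√p_null)``: with a null proportion of 0.005,
alternative 0.02 (the floor and ceiling of the national weekly mask-posting
series), α = 0.05 two-sided, and power 0.9, the required number of unique
image-posting users per county is n = ((z₀ − z_a)/h)² ≈ 519. Counties with
fewer users are screened out of the panel analysis.

Individual-level contrasts use a case-control design — keep every
mask-image tweet, subsample non-mask tweets per calendar day — analyzed
via crude 2×2 odds ratios with Wald intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerSpec",
    "cohen_h",
    "required_n",
    "eligible_counties",
    "case_control_sample",
    "TwoByTwoTable",
    "OddsRatioResult",
    "odds_ratio",
]


def cohen_h(p_null: float, p_alt: float) -> float:
    """Cohen's effect size for two proportions: 2(arcsin√p_alt − arcsin√p_null)."""
    for name, p in (("p_null", p_null), ("p_alt", p_alt)):
        if not (0.0 < p < 1.0):
            raise ValueError(f"{name} must be in (0, 1), got {p}")
    return 2.0 * (math.asin(math.sqrt(p_alt)) - math.asin(math.sqrt(p_null)))


@dataclass
class PowerSpec:
    """Two-proportion power specification with derived quantities.

    ``z_null`` is the two-sided critical quantile Φ⁻¹(1 − α/2); ``z_alt``
    is Φ⁻¹(β), the quantile the alternative-hypothesis mean must sit below
    to reach the target power.
    """

    p_null: float = 0.005
    p_alt: float = 0.02
    alpha: float = 0.05
    power: float = 0.9
    h: float = field(init=False)
    z_null: float = field(init=False)
    z_alt: float = field(init=False)
    n_required: int = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_null < self.p_alt < 1.0):
            raise ValueError("need 0 < p_null < p_alt < 1")
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.power < 1.0):
            raise ValueError("alpha and power must be in (0, 1)")
        self.h = cohen_h(self.p_null, self.p_alt)
        self.z_null = float(stats.norm.ppf(1.0 - self.alpha / 2.0))
        self.z_alt = float(stats.norm.ppf(1.0 - self.power))
        self.n_required = required_n(self)

    def to_dict(self) -> dict:
        return {
            "p_null": self.p_null,
            "p_alt": self.p_alt,
            "alpha": self.alpha,
            "power": self.power,
            "h": self.h,
            "z_null": self.z_null,
            "z_alt": self.z_alt,
            "n_required": self.n_required,
        }


def required_n(spec: PowerSpec) -> int:
    """n = ((z_null − z_alt)/h)², rounded to the nearest integer.

    Nearest-integer rounding (rather than the conventional ceiling)
    reproduces the printed value whether the z-quantiles enter at full
    precision (518.8) or truncated to three decimals (519.3 vs 518.8 —
    both round to 519).
    """
    h = cohen_h(spec.p_null, spec.p_alt)
    if h == 0:
        raise ValueError("zero effect size: required n is unbounded")
    z_null = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_alt = stats.norm.ppf(1.0 - spec.power)
    return int(round(((z_null - z_alt) / h) ** 2))


def eligible_counties(user_counts: pd.Series, n_required: int) -> list[str]:
    """Counties with at least ``n_required`` unique image-posting users.

    ``user_counts`` maps FIPS -> unique image-posting users over the whole
    study window. The boundary is inclusive.
    """
    counts = pd.Series(user_counts)
    return sorted(counts.index[counts >= n_required])


def case_control_sample(
    events: pd.DataFrame, per_day: int, seed: int, mask_col: str = "is_mask"
) -> pd.DataFrame:
    """All mask events plus <= per_day non-mask events per UTC calendar day.

    Non-mask tweets are drawn without replacement within each day; days
    with fewer than ``per_day`` non-mask tweets keep them all. Seeded and
    reproducible.
    """
    if per_day < 1:
        raise ValueError("per_day must be >= 1")
    rng = np.random.default_rng(seed)
    is_mask = events[mask_col].astype(bool)
    cases = events.loc[is_mask]
    controls = events.loc[~is_mask].copy()
    day = pd.to_datetime(controls["timestamp"]).dt.date
    sampled = []
    for _, group in controls.groupby(day, sort=True):
        if len(group) <= per_day:
            sampled.append(group)
        else:
            idx = rng.choice(len(group), size=per_day, replace=False)
            sampled.append(group.iloc[np.sort(idx)])
    pieces = [cases] + sampled
    return pd.concat(pieces).sort_index()


@dataclass(frozen=True)
class TwoByTwoTable:
    """Exposure-by-outcome counts: a/b exposed case/control, c/d unexposed."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("cell counts must be nonnegative")
        if sum(cells) == 0:
            raise ValueError("empty 2x2 table")


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    ci_level: float
    continuity_corrected: bool


def odds_ratio(table: TwoByTwoTable, ci_level: float = 0.95) -> OddsRatioResult:
    """OR = ad/bc with a Wald interval on the log scale.

    When any cell is zero, the Haldane–Anscombe correction adds 0.5 to all
    cells (flagged in the result). Two zero cells on the same diagonal
    leave the OR undefined and raise.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        raise ValueError("odds ratio undefined: two zero cells on a diagonal")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return OddsRatioResult(
        odds_ratio=or_,
        ci_low=math.exp(math.log(or_) - z * se),
        ci_high=math.exp(math.log(or_) + z * se),
        ci_level=ci_level,
        continuity_corrected=corrected,
    )
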