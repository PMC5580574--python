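"""Composite pollution index (PI).

Each indicator's annual mean ``Ci`` is standardized against its
first-class target ``Coi`` on a common pollution scale — ``Ci/Coi`` for
pollutants, ``Coi/Ci`` for benefit indicators (DO, transparency), and the
relative deviation from the interval midpoint for pH (``|Ci - 7.5| / 1.5``
for the 6-9 interval) — so that a sub-index of 1 marks a value exactly at
its target.  The composite index is the weighted average

    PI = sum_i  Wi * standardize_i(Ci)

with weights summing to one, so PI = 1 when every indicator sits at its
first-class standard and grows with pollution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .ahp import WeightScheme
from .standards import Direction, IndicatorDefinition, StandardsSet

__all__ = [
    "AnnualSeries",
    "PIResult",
    "standardize",
    "pollution_index",
    "aggregate_annual",
    "pi_series",
]


class PollutionIndexError(ValueError):
    """Invalid input to index computation."""


@dataclass(frozen=True)
class AnnualSeries:
    """Annual mean value per indicator for one year (means across sites)."""

    year: int
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = {k: float(v) for k, v in self.values.items()}
        object.__setattr__(self, "values", vals)
        for name, v in vals.items():
            if not math.isfinite(v) or v <= 0:
                raise PollutionIndexError(f"{self.year}/{name}: value must be positive, got {v}")


@dataclass(frozen=True)
class PIResult:
    """Composite index for one year with full per-indicator provenance."""

    year: int
    sub_indices: Mapping[str, float]
    weighted_terms: Mapping[str, float]
    pi: float


def standardize(definition: IndicatorDefinition, value: float) -> float:
    """Standardized (pollution-scale) sub-index of one measured value."""
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise PollutionIndexError(f"{definition.name}: value must be positive, got {value}")
    if definition.direction is Direction.RANGE:
        lo, hi = definition.interval
        mid = (lo + hi) / 2.0
        return abs(value - mid) / ((hi - lo) / 2.0)
    target = float(definition.first_class_value)  # type: ignore[arg-type]
    if definition.direction is Direction.POLLUTANT:
        return value / target
    return target / value


def pollution_index(
    series: AnnualSeries, standards: StandardsSet, weights: WeightScheme
) -> PIResult:
    """Weighted-average composite pollution index for one year."""
    sub: dict[str, float] = {}
    terms: dict[str, float] = {}
    for name in weights.indicators:
        if name not in series.values:
            raise PollutionIndexError(f"year {series.year}: missing value for {name!r}")
        if name not in standards:
            raise PollutionIndexError(f"no standard defined for weighted indicator {name!r}")
        s = standardize(standards[name], series.values[name])
        sub[name] = s
        terms[name] = weights[name] * s
    return PIResult(series.year, sub, terms, sum(terms.values()))


def aggregate_annual(records: pd.DataFrame) -> list[AnnualSeries]:
    """Collapse long-format monitoring records to annual means per indicator.

    ``records`` needs columns ``year``, ``indicator``, ``value`` (a ``site``
    column, if present, is averaged over).  Years are returned in ascending
    order.  An indicator missing in some year is an error: a weighted sum
    over a varying indicator set is not comparable across years.
    """
    required = {"year", "indicator", "value"}
    missing = required - set(records.columns)
    if missing:
        raise PollutionIndexError(f"records missing columns: {sorted(missing)}")
    if records.empty:
        raise PollutionIndexError("empty monitoring table")
    annual = (
        records.groupby(["year", "indicator"], sort=True)["value"].mean().unstack()
    )
    if annual.isna().any().any():
        gaps = [
            f"{ind}@{yr}"
            for yr in annual.index
            for ind in annual.columns
            if pd.isna(annual.loc[yr, ind])
        ]
        raise PollutionIndexError(f"missing indicator-years: {', '.join(gaps)}")
    return [
        AnnualSeries(int(year), annual.loc[year].to_dict()) for year in annual.index
    ]


def pi_series(
    series: Iterable[AnnualSeries] | pd.DataFrame,
    standards: StandardsSet,
    weights: WeightScheme,
) -> list[PIResult]:
    """Pollution index for every year of a monitoring dataset."""
    if isinstance(series, pd.DataFrame):
        series = aggregate_annual(series)
    return [pollution_index(s, standards, weights) for s in series]
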