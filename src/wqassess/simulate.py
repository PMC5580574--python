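"""Synthetic monitoring data and the bundled study fixture.

The generator emulates the statistical shape of multi-site lake/wetland
monitoring series: per indicator, positive concentrations scattered
lognormally around a median that tracks a configurable *exceedance ratio*
(the target mean of the pollution-scale sub-index Ci/Coi) through one of
four year-trend shapes.  Benefit indicators are inverted (higher exceedance
= lower concentration); pH is drawn uniformly inside or outside its 6-9
interval according to a compliance probability.  Identical spec + seed
yields an identical table.

``qilihai_fixture`` returns the published four-year (2010-2013) annual-mean
dataset for the eight-indicator Qilihai wetland assessment as a single
pseudo-site, together with the matching standards and weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ahp import WeightScheme
from .standards import Direction, StandardsSet, default_standards

__all__ = [
    "IndicatorScenario",
    "ScenarioSpec",
    "generate",
    "qilihai_fixture",
    "QILIHAI_ANNUAL_MEANS",
    "QILIHAI_WEIGHTS",
]

TREND_SHAPES = ("flat", "linear_up", "linear_down", "spike")


class ScenarioError(ValueError):
    """Invalid generator specification."""


@dataclass(frozen=True)
class IndicatorScenario:
    """Per-indicator generator knobs.

    exceedance: target mean of the pollution-scale sub-index (1.0 = exactly
        at the first-class standard on average; 20.0 = twenty-fold
        exceedance, the TP-like regime).
    noise: lognormal sigma of relative scatter (0 = deterministic).
    shape: year trend of the median exceedance — ``flat``; ``linear_up`` /
        ``linear_down`` ramp by ``trend_factor`` across the span;
        ``spike`` multiplies ``spike_year`` by ``trend_factor``.
    compliance_prob: range-type indicators only — probability a reading
        falls inside the acceptable interval.
    """

    exceedance: float = 1.0
    noise: float = 0.0
    shape: str = "flat"
    trend_factor: float = 3.0
    spike_year: int | None = None
    compliance_prob: float = 1.0

    def __post_init__(self) -> None:
        if not self.exceedance > 0:
            raise ScenarioError("exceedance must be positive")
        if self.noise < 0:
            raise ScenarioError("noise must be nonnegative")
        if self.shape not in TREND_SHAPES:
            raise ScenarioError(f"shape must be one of {TREND_SHAPES}")
        if self.shape == "spike" and self.spike_year is None:
            raise ScenarioError("spike shape needs spike_year")
        if not self.trend_factor > 0:
            raise ScenarioError("trend_factor must be positive")
        if not 0.0 <= self.compliance_prob <= 1.0:
            raise ScenarioError("compliance_prob must be in [0, 1]")


@dataclass(frozen=True)
class ScenarioSpec:
    """A multi-site, multi-year monitoring scenario."""

    years: tuple[int, int]  # inclusive
    n_sites: int
    indicators: dict[str, IndicatorScenario]
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.years
        if lo > hi:
            raise ScenarioError(f"invalid year range {self.years}")
        if self.n_sites < 1:
            raise ScenarioError("need at least one site")
        if not self.indicators:
            raise ScenarioError("no indicators in scenario")
        for name, sc in self.indicators.items():
            if sc.shape == "spike" and not lo <= sc.spike_year <= hi:
                raise ScenarioError(f"{name}: spike_year outside year range")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


def _median_exceedance(sc: IndicatorScenario, year: int, years: list[int]) -> float:
    """Trend-shaped exceedance for one year (flat = the spec value)."""
    if sc.shape == "flat":
        return sc.exceedance
    if sc.shape == "spike":
        return sc.exceedance * (sc.trend_factor if year == sc.spike_year else 1.0)
    span = max(len(years) - 1, 1)
    frac = years.index(year) / span
    if sc.shape == "linear_up":
        return sc.exceedance * (1.0 + (sc.trend_factor - 1.0) * frac)
    # linear_down: ramp from exceedance down to exceedance/trend_factor
    return sc.exceedance * (1.0 + (1.0 / sc.trend_factor - 1.0) * frac)


def generate(spec: ScenarioSpec, standards: StandardsSet | None = None) -> pd.DataFrame:
    """Draw a long-format monitoring table (site, year, indicator, value).

    For pollutant indicators values are lognormal with the mean of the
    sub-index Ci/Coi pinned to the (trend-shaped) exceedance ratio; benefit
    indicators mirror this so that the mean of Coi/Ci is pinned instead.
    Deterministic under (spec, seed).
    """
    if standards is None:
        standards = default_standards()
    for name in spec.indicators:
        if name not in standards:
            raise ScenarioError(f"indicator {name!r} not covered by standards")
    rng = np.random.default_rng(spec.seed)
    years = spec.year_list
    rows: list[tuple[str, int, str, float]] = []
    for name, sc in spec.indicators.items():
        defn = standards[name]
        for year in years:
            exc = _median_exceedance(sc, year, years)
            for site in range(1, spec.n_sites + 1):
                z = rng.standard_normal() if sc.noise > 0 else 0.0
                if defn.direction is Direction.RANGE:
                    lo, hi = defn.interval
                    inside = rng.random() < sc.compliance_prob
                    if inside:
                        value = rng.uniform(lo, hi)
                    else:
                        width = hi - lo
                        value = rng.uniform(hi, hi + 0.5 * width)
                elif defn.direction is Direction.POLLUTANT:
                    coi = float(defn.first_class_value)
                    # mean of value/coi equals exc: median = exc*coi*exp(-sigma^2/2)
                    median = exc * coi * math.exp(-0.5 * sc.noise**2)
                    value = median * math.exp(sc.noise * z)
                else:  # benefit: mean of coi/value equals exc
                    coi = float(defn.first_class_value)
                    median = (coi / exc) * math.exp(0.5 * sc.noise**2)
                    value = median * math.exp(sc.noise * z)
                rows.append((f"S{site:03d}", year, name, float(value)))
    return pd.DataFrame(rows, columns=["site", "year", "indicator", "value"])


# Published annual means (mg/L; transparency in m), years 2010-2013,
# single representative station around Bird Island.
QILIHAI_YEARS = (2010, 2011, 2012, 2013)

QILIHAI_ANNUAL_MEANS: dict[str, tuple[float, float, float, float]] = {
    "pH": (8.91, 8.65, 8.46, 8.75),
    "DO": (5.67, 9.43, 9.49, 9.20),
    "transparency": (0.38, 0.18, 1.23, 0.27),
    "COD": (22.30, 17.53, 28.33, 14.99),
    "TN": (1.69, 2.45, 2.43, 3.08),
    "TP": (0.192, 0.168, 0.268, 0.167),
    "petroleum": (0.79, 0.143, 0.122, 0.025),
    "chlorophyll_a": (0.087, 0.034, 0.093, 0.055),
}

QILIHAI_WEIGHTS: dict[str, float] = {
    "pH": 0.036,
    "DO": 0.107,
    "transparency": 0.107,
    "COD": 0.178,
    "TN": 0.178,
    "TP": 0.178,
    "petroleum": 0.059,
    "chlorophyll_a": 0.157,
}


def qilihai_fixture() -> tuple[pd.DataFrame, StandardsSet, WeightScheme]:
    """The published Qilihai 2010-2013 dataset, standards and weights.

    The monitoring table is long-format with a single pseudo-site
    (``QLH``), since only annual means were published.
    """
    rows = [
        ("QLH", year, name, vals[i])
        for name, vals in QILIHAI_ANNUAL_MEANS.items()
        for i, year in enumerate(QILIHAI_YEARS)
    ]
    table = pd.DataFrame(rows, columns=["site", "year", "indicator", "value"])
    return table, default_standards(), WeightScheme.direct(QILIHAI_WEIGHTS)
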