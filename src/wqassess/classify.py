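"""Pollution-level classification and time-series trend typing.

The annual PI series is split into three pollution levels of equal width
anchored at the smallest observed PI: *slight* ``[PImin, PImin+SD)``,
*moderate* ``[PImin+SD, PImin+2·SD)`` and *severe* ``[PImin+2·SD,
PImin+3·SD]``, where SD is the population standard deviation (divisor n)
of the PI series itself.  Each indicator's multi-year behaviour is further
labelled with one of four qualitative trend types — deteriorative,
floating, stable, improving — by a deterministic rule on the
pollution-scale sub-index series, and year-over-year changes are reported
as signed percentages.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .index import PIResult

__all__ = [
    "population_sd",
    "PollutionLevel",
    "PollutionLevelScheme",
    "LevelAssignment",
    "build_level_scheme",
    "assign_level",
    "percent_change",
    "TrendLabel",
    "TrendThresholds",
    "trend_label",
    "SeriesStats",
]


class ClassificationError(ValueError):
    """Invalid input to level or trend classification."""


def population_sd(values: Sequence[float]) -> float:
    """Standard deviation with divisor n (not the n-1 sample estimator)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ClassificationError("need at least one value")
    if not np.all(np.isfinite(arr)):
        raise ClassificationError("non-finite value in series")
    return float(np.sqrt(np.mean((arr - arr.mean()) ** 2)))


class PollutionLevel(str, enum.Enum):
    SLIGHT = "slight"
    MODERATE = "moderate"
    SEVERE = "severe"


@dataclass(frozen=True)
class PollutionLevelScheme:
    """Three SD-wide pollution levels anchored at the series minimum PI.

    Bounds are kept at full precision; any rounding (e.g. one decimal in
    printed reports) is display-only.
    """

    pi_min: float
    sd: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.pi_min) and math.isfinite(self.sd)):
            raise ClassificationError("non-finite scheme parameters")
        if self.sd <= 0:
            raise ClassificationError(
                "degenerate scheme: SD must be positive (constant PI series?)"
            )

    @property
    def intervals(self) -> dict[PollutionLevel, tuple[float, float]]:
        m, s = self.pi_min, self.sd
        return {
            PollutionLevel.SLIGHT: (m, m + s),
            PollutionLevel.MODERATE: (m + s, m + 2 * s),
            PollutionLevel.SEVERE: (m + 2 * s, m + 3 * s),
        }


@dataclass(frozen=True)
class LevelAssignment:
    level: PollutionLevel
    #: True when the PI fell outside [PImin, PImin+3·SD] and was clamped
    out_of_calibration: bool = False


def build_level_scheme(pi_series: Iterable[PIResult | float]) -> PollutionLevelScheme:
    """Derive the level scheme from a multi-year PI series (>= 2 years)."""
    pis = [p.pi if isinstance(p, PIResult) else float(p) for p in pi_series]
    if len(pis) < 2:
        raise ClassificationError("need at least two years of PI values")
    return PollutionLevelScheme(pi_min=min(pis), sd=population_sd(pis))


def assign_level(scheme: PollutionLevelScheme, pi: float) -> LevelAssignment:
    """Place a PI value in the scheme's levels (lower-inclusive intervals).

    Values outside the calibrated span are clamped to the nearest level and
    flagged, since the scheme defines no open-ended levels.
    """
    pi = float(pi)
    if not math.isfinite(pi):
        raise ClassificationError(f"non-finite PI {pi!r}")
    m, s = scheme.pi_min, scheme.sd
    if pi < m:
        return LevelAssignment(PollutionLevel.SLIGHT, out_of_calibration=True)
    if pi > m + 3 * s:
        return LevelAssignment(PollutionLevel.SEVERE, out_of_calibration=True)
    if pi < m + s:
        return LevelAssignment(PollutionLevel.SLIGHT)
    if pi < m + 2 * s:
        return LevelAssignment(PollutionLevel.MODERATE)
    return LevelAssignment(PollutionLevel.SEVERE)


def percent_change(earlier: float, later: float) -> float:
    """Signed percent change from ``earlier`` to ``later``: 100·(later−earlier)/earlier."""
    earlier, later = float(earlier), float(later)
    if not (math.isfinite(earlier) and math.isfinite(later)):
        raise ClassificationError("non-finite value")
    if earlier <= 0:
        raise ClassificationError(f"baseline must be positive, got {earlier}")
    return 100.0 * (later - earlier) / earlier


class TrendLabel(str, enum.Enum):
    DETERIORATIVE = "deteriorative"
    FLOATING = "floating"
    STABLE = "stable"
    IMPROVING = "improving"


@dataclass(frozen=True)
class TrendThresholds:
    """Tunable thresholds of the four-type trend rule.

    stable_cv: coefficient of variation (population SD / mean of the raw
        series) below which a standards-compliant series is *stable*.
    net_change: minimum |relative net change| first->last on the pollution
        scale for a monotone trend call (0.30 = 30%).
    dip_fraction: maximum size of a single counter-trend step, as a
        fraction of the series range, still tolerated in a monotone call.
    max_dips: how many counter-trend steps a monotone call tolerates.
    """

    stable_cv: float = 0.05
    net_change: float = 0.30
    dip_fraction: float = 0.05
    max_dips: int = 1


def _near_monotonic(diffs: np.ndarray, rng: float, sign: int, thr: TrendThresholds) -> bool:
    """sign=+1: non-decreasing up to tolerated dips; sign=-1: non-increasing."""
    counter = diffs * sign < 0
    if counter.sum() > thr.max_dips:
        return False
    if rng == 0:
        return True
    return bool(np.all(np.abs(diffs[counter]) <= thr.dip_fraction * rng))


def trend_label(
    sub_index_series: Sequence[float],
    compliant_throughout: bool,
    raw_values: Sequence[float] | None = None,
    thresholds: TrendThresholds = TrendThresholds(),
) -> TrendLabel:
    """Label a multi-year indicator series with one of four trend types.

    ``sub_index_series`` is on the pollution scale (up = worse).  The
    stability check uses the coefficient of variation of ``raw_values``
    (the measured series) when given — relevant for range-type indicators
    like pH whose sub-index exaggerates relative variation — otherwise of
    the sub-index series itself.

    Rule: *stable* if the CV is below ``stable_cv`` and the indicator met
    the standard in every year; else *improving* (resp. *deteriorative*)
    if the series is near-monotonic down (resp. up) with a net change of at
    least ``net_change`` in magnitude; else *floating*.
    """
    sub = np.asarray(list(sub_index_series), dtype=float)
    if sub.size < 3:
        raise ClassificationError("need at least three time points")
    if not np.all(np.isfinite(sub)) or np.any(sub < 0):
        raise ClassificationError("sub-indices must be finite and nonnegative")
    basis = np.asarray(list(raw_values), dtype=float) if raw_values is not None else sub
    if basis.size != sub.size:
        raise ClassificationError("raw series length differs from sub-index series")

    mean = basis.mean()
    cv = population_sd(basis) / mean if mean > 0 else math.inf
    if cv < thresholds.stable_cv and compliant_throughout:
        return TrendLabel.STABLE

    if sub[0] <= 0:
        return TrendLabel.FLOATING
    net = (sub[-1] - sub[0]) / sub[0]
    diffs = np.diff(sub)
    rng = float(sub.max() - sub.min())
    if net <= -thresholds.net_change and _near_monotonic(diffs, rng, -1, thresholds):
        return TrendLabel.IMPROVING
    if net >= thresholds.net_change and _near_monotonic(diffs, rng, +1, thresholds):
        return TrendLabel.DETERIORATIVE
    return TrendLabel.FLOATING


@dataclass(frozen=True)
class SeriesStats:
    """Per-indicator series summary: values in year order plus population SD."""

    indicator: str
    years: tuple[int, ...]
    values: tuple[float, ...]

    @property
    def sd(self) -> float:
        return population_sd(self.values)

    def year_over_year(self) -> dict[tuple[int, int], float]:
        """Percent change between each consecutive pair of years."""
        return {
            (y0, y1): percent_change(v0, v1)
            for (y0, v0), (y1, v1) in zip(
                zip(self.years, self.values), zip(self.years[1:], self.values[1:])
            )
        }
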