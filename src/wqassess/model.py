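"""Model/Results interface for the full water-quality assessment.

``WaterQualityAssessment`` bundles a long-format monitoring table with a
standards set, a weight scheme and the analysis options; ``fit()`` runs
every stage — annual aggregation, single-factor classification,
first-class compliance, the composite pollution index per year, the
SD-based level scheme, level assignment, trend typing and year-over-year
percent changes — and returns an ``AssessmentResults`` carrying the full
numeric record plus a human-readable ``summary()``.

Example
-------
>>> from wqassess import WaterQualityAssessment
>>> res = WaterQualityAssessment.qilihai().fit()
>>> round(res.pi[2012], 2)
15.26
>>> res.levels[2012].level.value
'severe'
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .ahp import WeightScheme
from .classify import (
    LevelAssignment,
    PollutionLevelScheme,
    SeriesStats,
    TrendLabel,
    assign_level,
    population_sd,
    trend_label,
)
from .index import AnnualSeries, PIResult, aggregate_annual, pollution_index
from .io import AssessmentConfig, read_monitoring_table
from .simulate import qilihai_fixture
from .standards import StandardsSet, WaterQualityClass, default_standards

__all__ = ["WaterQualityAssessment", "AssessmentResults", "run_assessment"]


class WaterQualityAssessment:
    """Composite pollution-index assessment of a monitoring dataset.

    Parameters
    ----------
    data : pandas.DataFrame
        Long-format records with columns ``site, year, indicator, value``.
    standards : StandardsSet, optional
        Indicator definitions and class-limit tables; bundled defaults
        (lake/reservoir nutrient columns) if omitted.
    weights : WeightScheme, optional
        Indicator weights summing to one; the bundled expert scheme if
        omitted.
    config : AssessmentConfig, optional
        Analysis options (aggregation, SD divisor, trend thresholds).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        standards: StandardsSet | None = None,
        weights: WeightScheme | None = None,
        config: AssessmentConfig | None = None,
    ) -> None:
        self.standards = standards if standards is not None else default_standards()
        if weights is None:
            _, _, weights = qilihai_fixture()
        self.weights = weights
        self.config = config if config is not None else AssessmentConfig()
        self.data = data.copy()
        self.annual: list[AnnualSeries] = aggregate_annual(self.data)
        if len(self.annual) < 2:
            raise ValueError("assessment needs at least two years of data")

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        standards: StandardsSet | None = None,
        weights: WeightScheme | None = None,
        config: AssessmentConfig | None = None,
    ) -> "WaterQualityAssessment":
        return cls(read_monitoring_table(path), standards, weights, config)

    @classmethod
    def qilihai(cls, config: AssessmentConfig | None = None) -> "WaterQualityAssessment":
        """The model pre-loaded with the published 2010-2013 dataset."""
        table, standards, weights = qilihai_fixture()
        return cls(table, standards, weights, config)

    def _sd(self, values) -> float:
        if self.config.sd_divisor == "population":
            return population_sd(values)
        arr = np.asarray(list(values), dtype=float)
        return float(arr.std(ddof=1))

    def fit(self) -> "AssessmentResults":
        """Run every assessment stage and return the results object."""
        years = [s.year for s in self.annual]

        pi_results = [
            pollution_index(s, self.standards, self.weights) for s in self.annual
        ]
        pis = [r.pi for r in pi_results]
        scheme = PollutionLevelScheme(pi_min=min(pis), sd=self._sd(pis))
        levels = {r.year: assign_level(scheme, r.pi) for r in pi_results}

        indicators = self.weights.indicators
        classes: dict[str, dict[int, WaterQualityClass | None]] = {}
        compliance: dict[str, dict[int, bool]] = {}
        for name in indicators:
            classes[name] = {}
            compliance[name] = {}
            for s in self.annual:
                v = s.values[name]
                compliance[name][s.year] = self.standards.compliant(name, v)
                classes[name][s.year] = (
                    self.standards.classify(name, v)
                    if self.standards.has_class_table(name)
                    else None
                )

        stats = {
            name: SeriesStats(
                name,
                tuple(years),
                tuple(s.values[name] for s in self.annual),
            )
            for name in indicators
        }
        trends = {}
        for name in indicators:
            sub = [r.sub_indices[name] for r in pi_results]
            trends[name] = trend_label(
                sub,
                compliant_throughout=all(compliance[name].values()),
                raw_values=stats[name].values,
                thresholds=self.config.trend_thresholds,
            )

        return AssessmentResults(
            model=self,
            years=tuple(years),
            pi_results=tuple(pi_results),
            level_scheme=scheme,
            levels=levels,
            single_factor=classes,
            compliance=compliance,
            series_stats=stats,
            trends=trends,
        )


@dataclass(frozen=True)
class AssessmentResults:
    """Fitted assessment: indices, levels, classes, trends and reports."""

    model: WaterQualityAssessment
    years: tuple[int, ...]
    pi_results: tuple[PIResult, ...]
    level_scheme: PollutionLevelScheme
    levels: dict[int, LevelAssignment]
    single_factor: dict[str, dict[int, WaterQualityClass | None]]
    compliance: dict[str, dict[int, bool]]
    series_stats: dict[str, SeriesStats]
    trends: dict[str, TrendLabel]

    @property
    def pi(self) -> dict[int, float]:
        """Composite pollution index by year."""
        return {r.year: r.pi for r in self.pi_results}

    @property
    def pi_sd(self) -> float:
        """Spread (per the configured divisor) of the annual PI series."""
        return self.level_scheme.sd

    def pi_frame(self) -> pd.DataFrame:
        """Per-year sub-indices and PI as a tidy frame (years as rows)."""
        rows = {}
        for r in self.pi_results:
            row = dict(r.sub_indices)
            row["PI"] = r.pi
            row["level"] = self.levels[r.year].level.value
            rows[r.year] = row
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.index.name = "year"
        return frame

    def single_factor_frame(self) -> pd.DataFrame:
        """Per indicator-year: value, quality class, first-class compliance."""
        rows = []
        for name, stats in self.series_stats.items():
            for year, value in zip(stats.years, stats.values):
                cls = self.single_factor[name][year]
                rows.append(
                    {
                        "indicator": name,
                        "year": year,
                        "value": value,
                        "class": str(cls) if cls is not None else "",
                        "first_class_compliant": self.compliance[name][year],
                    }
                )
        return pd.DataFrame(rows)

    def percent_change_frame(self) -> pd.DataFrame:
        """Year-over-year percent change per indicator (raw measured scale)."""
        rows = [
            {"indicator": name, "from": y0, "to": y1, "percent_change": pc}
            for name, stats in self.series_stats.items()
            for (y0, y1), pc in stats.year_over_year().items()
        ]
        return pd.DataFrame(rows)

    def worst_class(self, year: int) -> WaterQualityClass:
        """Single-factor overall verdict: the worst indicator class of a year."""
        classed = [
            c[year] for c in self.single_factor.values() if c[year] is not None
        ]
        if not classed:
            raise ValueError(f"no class-table indicators assessed in {year}")
        return max(classed)

    def summary(self) -> str:
        """Human-readable report; every number is recomputable from the results."""
        nd = self.model.config.round_bounds_decimals
        lines = []
        lines.append("Composite pollution-index assessment")
        lines.append("=" * 52)
        lines.append(
            f"Years {self.years[0]}-{self.years[-1]}, "
            f"{len(self.series_stats)} indicators, "
            f"weights source: {self.model.weights.source.value}"
        )
        lines.append("")
        lines.append("Pollution levels (PImin anchored, SD-wide):")
        lines.append(f"  PImin = {self.level_scheme.pi_min:.2f}, SD = {self.level_scheme.sd:.2f}")
        for level, (lo, hi) in self.level_scheme.intervals.items():
            lines.append(f"  {level.value:<9} {round(lo, nd):g} - {round(hi, nd):g}")
        lines.append("")
        lines.append(f"{'year':>6} {'PI':>8}  level")
        for r in self.pi_results:
            flag = " (out of calibration)" if self.levels[r.year].out_of_calibration else ""
            lines.append(
                f"{r.year:>6} {r.pi:>8.2f}  {self.levels[r.year].level.value}{flag}"
            )
        lines.append("")
        lines.append(f"{'indicator':<14} {'trend':<14} {'SD':>8}  classes by year")
        for name, stats in self.series_stats.items():
            cls = " ".join(
                str(self.single_factor[name][y]) if self.single_factor[name][y] else "-"
                for y in self.years
            )
            lines.append(
                f"{name:<14} {self.trends[name].value:<14} {stats.sd:>8.2f}  {cls}"
            )
        return "\n".join(lines)

    def to_csv(self, output_dir: str | Path) -> dict[str, Path]:
        """Write the delimited report files; returns name -> path."""
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "pi": out / "pi_by_year.csv",
            "single_factor": out / "single_factor.csv",
            "percent_change": out / "percent_change.csv",
        }
        self.pi_frame().to_csv(paths["pi"])
        self.single_factor_frame().to_csv(paths["single_factor"], index=False)
        self.percent_change_frame().to_csv(paths["percent_change"], index=False)
        return paths

    def plot_pi(self, ax=None):
        """Plot the annual PI curve with the level bands shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        shades = {"slight": "#d9ead3", "moderate": "#fce5cd", "severe": "#f4cccc"}
        for level, (lo, hi) in self.level_scheme.intervals.items():
            ax.axhspan(lo, hi, color=shades[level.value], alpha=0.8, label=level.value)
        ax.plot(self.years, [r.pi for r in self.pi_results], "o-", color="tab:blue")
        ax.set_xlabel("year")
        ax.set_ylabel("pollution index (PI)")
        ax.set_xticks(list(self.years))
        ax.legend(loc="best", fontsize="small")
        return ax


def run_assessment(config: AssessmentConfig) -> AssessmentResults:
    """Execute the end-to-end assessment described by a config.

    Loads the monitoring table, standards and weights (bundled defaults
    where paths are omitted), fits the model, and writes report files if
    an output directory is configured.
    """
    from .io import load_weight_config
    from .standards import load_standards

    if config.monitoring_path is None:
        table, _, _ = qilihai_fixture()
    else:
        table = read_monitoring_table(config.monitoring_path)
    standards = load_standards(config.standards_path)
    if config.weights_path is None:
        _, _, weights = qilihai_fixture()
    else:
        weights = load_weight_config(config.weights_path)
    results = WaterQualityAssessment(table, standards, weights, config).fit()
    if config.output_dir is not None:
        results.to_csv(config.output_dir)
    return results
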