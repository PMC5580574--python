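"""Reading and writing monitoring tables, weight configs and reports.

The canonical on-disk format is a long (tidy) delimited table with header
``site,year,indicator,value`` — one row per measurement.  A converter is
provided for the wide layout common in published summary tables (one row
per indicator, one column per year).  All validation errors carry the
offending line number.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .ahp import WeightScheme, matrix_from_scores, weights_from_matrix
from .classify import TrendThresholds
from .standards import KNOWN_INDICATORS

__all__ = [
    "MonitoringDataError",
    "read_monitoring_table",
    "write_monitoring_table",
    "wide_to_long",
    "load_weight_config",
    "AssessmentConfig",
]

_COLUMNS = ("site", "year", "indicator", "value")


class MonitoringDataError(ValueError):
    """Malformed monitoring table; message carries the offending line."""


def read_monitoring_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format monitoring table.

    Rejects unknown indicators, non-positive or non-numeric values,
    malformed rows and duplicate (site, year, indicator) triples, each
    with the line number.
    """
    path = Path(path)
    rows: list[tuple[str, int, str, float]] = []
    seen: dict[tuple[str, int, str], int] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise MonitoringDataError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        if header != list(_COLUMNS):
            raise MonitoringDataError(
                f"{path}:1: expected header {','.join(_COLUMNS)}, got {','.join(header)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4:
                raise MonitoringDataError(
                    f"{path}:{lineno}: expected 4 fields, got {len(row)}"
                )
            site, year_s, indicator, value_s = (c.strip() for c in row)
            if indicator not in KNOWN_INDICATORS:
                raise MonitoringDataError(
                    f"{path}:{lineno}: unknown indicator {indicator!r}"
                )
            try:
                year = int(year_s)
            except ValueError:
                raise MonitoringDataError(
                    f"{path}:{lineno}: non-integer year {year_s!r}"
                ) from None
            try:
                value = float(value_s)
            except ValueError:
                raise MonitoringDataError(
                    f"{path}:{lineno}: non-numeric value {value_s!r}"
                ) from None
            if not value > 0:
                raise MonitoringDataError(
                    f"{path}:{lineno}: value must be positive, got {value}"
                )
            key = (site, year, indicator)
            if key in seen:
                raise MonitoringDataError(
                    f"{path}:{lineno}: duplicate record for {key} "
                    f"(first at line {seen[key]})"
                )
            seen[key] = lineno
            rows.append((site, year, indicator, value))
    if not rows:
        raise MonitoringDataError(f"{path}: no data rows")
    return pd.DataFrame(rows, columns=list(_COLUMNS))


def write_monitoring_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format monitoring table; round-trips via read_monitoring_table."""
    records = records.loc[:, list(_COLUMNS)]
    records.to_csv(path, index=False)


def wide_to_long(
    wide: pd.DataFrame, site: str = "S001", indicator_column: str = "indicator"
) -> pd.DataFrame:
    """Convert a wide table (indicator rows × year columns) to long format."""
    if indicator_column not in wide.columns:
        raise MonitoringDataError(f"wide table needs an {indicator_column!r} column")
    year_cols = [c for c in wide.columns if c != indicator_column]
    try:
        years = {c: int(c) for c in year_cols}
    except ValueError as exc:
        raise MonitoringDataError(f"non-year column in wide table: {exc}") from None
    long = wide.melt(
        id_vars=[indicator_column], var_name="year", value_name="value"
    ).rename(columns={indicator_column: "indicator"})
    long["year"] = long["year"].map(years)
    long.insert(0, "site", site)
    return long.loc[:, list(_COLUMNS)].sort_values(["indicator", "year"], kind="stable").reset_index(drop=True)


def load_weight_config(path: str | Path) -> WeightScheme:
    """Load a weight scheme from YAML.

    The file provides either a ``weights:`` block (indicator -> number,
    used directly) or an ``ahp_scores:`` block (indicator -> 1..5
    importance score, run through the AHP machinery); a file providing
    both is refused as ambiguous.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise MonitoringDataError(f"{path}: weight config must be a mapping")
    has_w = "weights" in raw
    has_s = "ahp_scores" in raw
    if has_w and has_s:
        raise MonitoringDataError(
            f"{path}: provide either 'weights' or 'ahp_scores', not both"
        )
    if has_w:
        return WeightScheme.direct(raw["weights"])
    if has_s:
        return weights_from_matrix(matrix_from_scores(raw["ahp_scores"]))
    raise MonitoringDataError(f"{path}: need a 'weights' or 'ahp_scores' block")


@dataclass
class AssessmentConfig:
    """End-to-end assessment options with the defaults used throughout.

    The analysis conventions that matter are explicit here so deviations
    are visible: arithmetic-mean annual aggregation, population-SD level
    scheme, display-only rounding of level bounds, and the trend-rule
    thresholds.
    """

    monitoring_path: str | None = None
    standards_path: str | None = None  # None = bundled defaults
    weights_path: str | None = None  # None = bundled expert weights
    output_dir: str | None = None
    aggregation: str = "mean"
    sd_divisor: str = "population"
    round_bounds_decimals: int = 1  # display only
    trend_thresholds: TrendThresholds = field(default_factory=TrendThresholds)

    def __post_init__(self) -> None:
        if self.aggregation != "mean":
            raise MonitoringDataError(
                f"unsupported aggregation {self.aggregation!r} (only 'mean')"
            )
        if self.sd_divisor not in ("population", "sample"):
            raise MonitoringDataError("sd_divisor must be 'population' or 'sample'")
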