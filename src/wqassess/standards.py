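"""Indicator definitions and surface-water quality class tables.

A monitored indicator is described by its *direction* — whether a higher
reading means more pollution (``pollutant``: COD, TN, TP, petroleum,
chlorophyll-a), less pollution (``benefit``: DO, transparency), or whether
departure from an acceptable interval is what matters (``range``: pH) —
together with a first-class target value ``Coi`` and, where the national
standard defines one, a five-class limit table (class I best, class V
worst).  Single-factor evaluation assigns a reading the best class whose
limit it satisfies; a reading that fails even class V falls in the extra
"worse than V" category.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Union

import yaml

__all__ = [
    "Direction",
    "Category",
    "WaterQualityClass",
    "IndicatorDefinition",
    "ClassLimitTable",
    "StandardsSet",
    "classify_value",
    "check_first_class_compliance",
    "load_standards",
    "save_standards",
    "default_standards",
    "KNOWN_INDICATORS",
]

KNOWN_INDICATORS = (
    "pH",
    "DO",
    "transparency",
    "COD",
    "TN",
    "TP",
    "petroleum",
    "chlorophyll_a",
)


class StandardsError(ValueError):
    """Invalid indicator definition, limit table, or value."""


class Direction(str, enum.Enum):
    POLLUTANT = "pollutant"  # higher is worse
    BENEFIT = "benefit"      # lower is worse
    RANGE = "range"          # deviation from an interval is worse


class Category(str, enum.Enum):
    GENERAL = "general"
    POLLUTION = "pollution"
    BIOLOGICAL = "biological"


class WaterQualityClass(enum.IntEnum):
    """Surface-water quality classes, ordered best (I) to worst.

    ``WORSE_THAN_V`` is the conventional sixth category for readings that
    exceed even the class-V limit; the standard itself defines no class
    for them.
    """

    I = 1
    II = 2
    III = 3
    IV = 4
    V = 5
    WORSE_THAN_V = 6

    def __str__(self) -> str:  # pragma: no cover - display helper
        return "worse than V" if self is WaterQualityClass.WORSE_THAN_V else self.name


#: the five real classes, in order
_CLASSES = tuple(WaterQualityClass)[:5]

Interval = tuple[float, float]
FirstClassValue = Union[float, Interval]


@dataclass(frozen=True)
class IndicatorDefinition:
    """One monitored quantity and its first-class target ``Coi``."""

    name: str
    units: str
    direction: Direction
    category: Category
    first_class_value: FirstClassValue

    def __post_init__(self) -> None:
        if self.name not in KNOWN_INDICATORS:
            raise StandardsError(
                f"unknown indicator {self.name!r}; expected one of {KNOWN_INDICATORS}"
            )
        if self.direction is Direction.RANGE:
            try:
                lo, hi = self.first_class_value  # type: ignore[misc]
            except TypeError:
                raise StandardsError(
                    f"{self.name}: range-type indicator needs an interval target"
                ) from None
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise StandardsError(f"{self.name}: interval must satisfy lo < hi")
        else:
            v = self.first_class_value
            if not isinstance(v, (int, float)) or not math.isfinite(v) or v <= 0:
                raise StandardsError(
                    f"{self.name}: first-class value must be a positive number, got {v!r}"
                )

    @property
    def interval(self) -> Interval:
        if self.direction is not Direction.RANGE:
            raise StandardsError(f"{self.name} is not a range-type indicator")
        lo, hi = self.first_class_value  # type: ignore[misc]
        return float(lo), float(hi)


@dataclass(frozen=True)
class ClassLimitTable:
    """Five-class limit table for one indicator.

    The meaning of a limit depends on direction: an upper bound for
    pollutants, a lower bound for benefit indicators.
    """

    indicator: str
    limits: Mapping[WaterQualityClass, float]
    direction: Direction = Direction.POLLUTANT

    def __post_init__(self) -> None:
        if set(self.limits) != set(_CLASSES):
            raise StandardsError(
                f"{self.indicator}: limit table must cover exactly classes I..V"
            )
        vals = [float(self.limits[c]) for c in _CLASSES]
        if any(not math.isfinite(v) or v <= 0 for v in vals):
            raise StandardsError(f"{self.indicator}: limits must be positive and finite")
        if self.direction is Direction.POLLUTANT:
            if any(a > b for a, b in zip(vals, vals[1:])):
                raise StandardsError(
                    f"{self.indicator}: pollutant limits must be non-decreasing I..V"
                )
        elif self.direction is Direction.BENEFIT:
            if any(a < b for a, b in zip(vals, vals[1:])):
                raise StandardsError(
                    f"{self.indicator}: benefit limits must be non-increasing I..V"
                )

    def limit(self, cls: WaterQualityClass) -> float:
        return float(self.limits[cls])


def _check_value(definition: IndicatorDefinition, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise StandardsError(f"{definition.name}: non-finite value {value!r}")
    if value <= 0:
        raise StandardsError(f"{definition.name}: value must be positive, got {value}")
    return value


def classify_value(
    definition: IndicatorDefinition,
    limits: ClassLimitTable | None,
    value: float,
) -> WaterQualityClass:
    """Assign ``value`` the best water-quality class whose limit it satisfies.

    A value exactly at a class limit belongs to the better class (``<=`` for
    pollutants, ``>=`` for benefit indicators).  Range-type indicators are
    class I inside their interval and worse-than-V outside.  Returns
    ``WORSE_THAN_V`` when no class-V limit is met.
    """
    value = _check_value(definition, value)
    if definition.direction is Direction.RANGE:
        lo, hi = definition.interval
        return WaterQualityClass.I if lo <= value <= hi else WaterQualityClass.WORSE_THAN_V
    if limits is None:
        raise StandardsError(f"{definition.name}: no class-limit table available")
    if limits.indicator != definition.name:
        raise StandardsError(
            f"limit table for {limits.indicator!r} does not match indicator "
            f"{definition.name!r}"
        )
    for cls in _CLASSES:
        bound = limits.limit(cls)
        ok = value <= bound if definition.direction is Direction.POLLUTANT else value >= bound
        if ok:
            return cls
    return WaterQualityClass.WORSE_THAN_V


def check_first_class_compliance(definition: IndicatorDefinition, value: float) -> bool:
    """True iff ``value`` meets the first-class target under the indicator's direction."""
    value = _check_value(definition, value)
    if definition.direction is Direction.RANGE:
        lo, hi = definition.interval
        return lo <= value <= hi
    target = float(definition.first_class_value)  # type: ignore[arg-type]
    if definition.direction is Direction.POLLUTANT:
        return value <= target
    return value >= target


@dataclass
class StandardsSet:
    """A coherent set of indicator definitions with their class-limit tables."""

    definitions: dict[str, IndicatorDefinition]
    class_limits: dict[str, ClassLimitTable] = field(default_factory=dict)
    alt_class_limits: dict[str, dict[str, ClassLimitTable]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, table in self.class_limits.items():
            if name not in self.definitions:
                raise StandardsError(f"limit table for undefined indicator {name!r}")
            if table.indicator != name:
                raise StandardsError(f"limit table key {name!r} != table.indicator")

    def __contains__(self, name: str) -> bool:
        return name in self.definitions

    def __getitem__(self, name: str) -> IndicatorDefinition:
        try:
            return self.definitions[name]
        except KeyError:
            raise StandardsError(f"indicator {name!r} not in standards set") from None

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(self.definitions)

    def limits_for(self, name: str) -> ClassLimitTable | None:
        return self.class_limits.get(name)

    def classify(self, name: str, value: float) -> WaterQualityClass:
        return classify_value(self[name], self.limits_for(name), value)

    def compliant(self, name: str, value: float) -> bool:
        return check_first_class_compliance(self[name], value)

    def has_class_table(self, name: str) -> bool:
        defn = self[name]
        return defn.direction is Direction.RANGE or name in self.class_limits

    def using_alt_limits(self, name: str, variant: str) -> "StandardsSet":
        """Return a copy where ``name`` uses the named alternative limit column."""
        try:
            table = self.alt_class_limits[name][variant]
        except KeyError:
            raise StandardsError(
                f"no alternative limit column {variant!r} for {name!r}"
            ) from None
        limits = dict(self.class_limits)
        limits[name] = table
        return StandardsSet(dict(self.definitions), limits, dict(self.alt_class_limits))


def _parse_limits(name: str, raw: Mapping[str, float], direction: Direction) -> ClassLimitTable:
    try:
        limits = {WaterQualityClass[c]: float(v) for c, v in raw.items()}
    except KeyError as exc:
        raise StandardsError(f"{name}: unknown class label {exc}") from None
    return ClassLimitTable(name, limits, direction)


def load_standards(path: str | None = None) -> StandardsSet:
    """Load a standards set from a YAML config; the bundled default if no path."""
    if path is None:
        source = resources.files("wqassess.data").joinpath("standards_gb3838.yaml")
        raw = yaml.safe_load(source.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "indicators" not in raw:
        raise StandardsError("standards config must have a top-level 'indicators' map")
    definitions: dict[str, IndicatorDefinition] = {}
    class_limits: dict[str, ClassLimitTable] = {}
    alt: dict[str, dict[str, ClassLimitTable]] = {}
    for name, block in raw["indicators"].items():
        direction = Direction(block["direction"])
        fcv = block["first_class_value"]
        if direction is Direction.RANGE:
            if isinstance(fcv, str):  # "6-9" shorthand
                lo, hi = (float(x) for x in fcv.split("-"))
            else:
                lo, hi = (float(x) for x in fcv)
            fcv = (lo, hi)
        else:
            fcv = float(fcv)
        definitions[name] = IndicatorDefinition(
            name=name,
            units=str(block.get("units", "")),
            direction=direction,
            category=Category(block["category"]),
            first_class_value=fcv,
        )
        if "class_limits" in block:
            class_limits[name] = _parse_limits(name, block["class_limits"], direction)
        for variant, tbl in (block.get("alt_class_limits") or {}).items():
            alt.setdefault(name, {})[variant] = _parse_limits(name, tbl, direction)
    return StandardsSet(definitions, class_limits, alt)


def save_standards(standards: StandardsSet, path: str) -> None:
    """Write a standards set back to YAML such that ``load_standards`` round-trips."""
    out: dict = {"indicators": {}}
    for name, defn in standards.definitions.items():
        block: dict = {
            "units": defn.units,
            "direction": defn.direction.value,
            "category": defn.category.value,
        }
        if defn.direction is Direction.RANGE:
            block["first_class_value"] = list(defn.interval)
        else:
            block["first_class_value"] = float(defn.first_class_value)  # type: ignore[arg-type]
        table = standards.class_limits.get(name)
        if table is not None:
            block["class_limits"] = {c.name: float(table.limits[c]) for c in _CLASSES}
        for variant, tbl in standards.alt_class_limits.get(name, {}).items():
            block.setdefault("alt_class_limits", {})[variant] = {
                c.name: float(tbl.limits[c]) for c in _CLASSES
            }
        out["indicators"][name] = block
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def default_standards() -> StandardsSet:
    """The bundled standards set (lake/reservoir nutrient columns)."""
    return load_standards(None)
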