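"""Dinius multiplicative Water Quality Index (WQI).

The index aggregates 13 measured parameters (11 physicochemical, 2
microbiological) into a single 0-100 score as a weighted geometric product

    WQI = prod_i I_i ** w_i,    sum_i w_i = 1,

where each subindex ``I_i`` maps one raw measurement (or, for temperature,
the water/atmospheric pair) onto a 0-100 quality scale through a named,
parameterized transform.  The transforms and weights are configuration data:
the defaults shipped here are transcribed from Dinius's 1987 formulation and
should be treated as a reconstruction — the product machinery, clamping and
category logic are the tested contract, not the constants.

Scores are graded on a general scale and on water-use-specific scales
(public water supply, agriculture, ...), each an ordered list of categories
with inclusive lower bounds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "PhyschemRecord",
    "SubindexSpec",
    "WQIResult",
    "UseCategoryTable",
    "DEFAULT_SUBINDEX_SPECS",
    "DEFAULT_GENERAL_SCHEME",
    "DEFAULT_USE_TABLE",
    "compute_subindex",
    "compute_wqi",
    "classify_general",
    "classify_by_use",
]

WEIGHT_SUM_TOL = 1e-6

#: Floor applied before log/power transforms of coliform counts so a 0 MPN
#: record maps to the best subindex instead of diverging.
COLIFORM_FLOOR = 1.0


class ConfigError(ValueError):
    """Raised for invalid subindex/weight configuration."""


@dataclass(frozen=True)
class PhyschemRecord:
    """The 13 Dinius parameters for one site x season.

    Units: temperatures degC; dissolved_oxygen, nitrates (as NO3), bod5,
    chlorides mg/L; alkalinity and hardness mg/L CaCO3; conductivity uS/cm;
    color Pt-Co units; coliforms MPN/100 mL.
    """

    site_id: str
    season: str
    atmospheric_temperature: float
    water_temperature: float
    dissolved_oxygen: float
    pH: float
    conductivity: float
    nitrates: float
    alkalinity: float
    hardness: float
    chlorides: float
    color: float
    bod5: float
    total_coliforms: float
    fecal_coliforms: float

    def __post_init__(self) -> None:
        nonneg = (
            "dissolved_oxygen", "conductivity", "nitrates", "alkalinity",
            "hardness", "chlorides", "color", "bod5",
            "total_coliforms", "fecal_coliforms",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0 <= self.pH <= 14:
            raise ValueError(f"pH must be in [0, 14], got {self.pH}")

    def get(self, parameter: str) -> float:
        try:
            value = getattr(self, parameter)
        except AttributeError:
            raise KeyError(f"record has no parameter {parameter!r}") from None
        if not math.isfinite(value):
            raise ValueError(f"{parameter} is not finite: {value!r}")
        return float(value)


PARAMETERS = tuple(
    f for f in PhyschemRecord.__dataclass_fields__ if f not in ("site_id", "season")
)


# ---------------------------------------------------------------------------
# Transform registry
# ---------------------------------------------------------------------------

def _t_linear(record: PhyschemRecord, p: Mapping, parameter: str) -> float:
    return p.get("slope", 1.0) * record.get(parameter) + p.get("intercept", 0.0)


def _t_power(record: PhyschemRecord, p: Mapping, parameter: str) -> float:
    # a * x**b; a floor guards decreasing-power transforms against x = 0
    x = max(record.get(parameter), p.get("floor", 1e-9))
    return p["a"] * x ** p["b"]


def _t_exp10(record: PhyschemRecord, p: Mapping, parameter: str) -> float:
    # 10 ** (a + b*x)
    return 10.0 ** (p["a"] + p["b"] * record.get(parameter))


def _t_piecewise_linear(record: PhyschemRecord, p: Mapping, parameter: str) -> float:
    # linear interpolation through sorted (x, y) knots, flat extrapolation
    knots = sorted((float(x), float(y)) for x, y in p["knots"])
    x = record.get(parameter)
    if x <= knots[0][0]:
        return knots[0][1]
    for (x0, y0), (x1, y1) in zip(knots, knots[1:]):
        if x <= x1:
            return y0 + (y1 - y0) * (x - x0) / (x1 - x0)
    return knots[-1][1]


def _t_ph_dinius(record: PhyschemRecord, p: Mapping, parameter: str) -> float:
    # best quality on a central plateau, log-linear decay to either side
    x = record.get(parameter)
    lo = p.get("plateau_low", 6.9)
    hi = p.get("plateau_high", 7.1)
    if x < lo:
        return 10.0 ** (p["acid_a"] + p["acid_b"] * x)
    if x > hi:
        return 10.0 ** (p["alk_a"] + p["alk_b"] * x)
    return 100.0


def _t_temperature_difference(record: PhyschemRecord, p: Mapping, parameter: str) -> float:
    # two-argument transform: decays with |water - atmospheric| temperature
    d = abs(record.get("water_temperature") - record.get("atmospheric_temperature"))
    return 10.0 ** (p["a"] + p["b"] * d)


def _t_oxygen_saturation(record: PhyschemRecord, p: Mapping, parameter: str) -> float:
    # two-argument transform: DO as percent of temperature-dependent
    # saturation (freshwater, sea-level polynomial), then linear
    t = record.get("water_temperature")
    do_sat = 14.62 - 0.3898 * t + 0.006969 * t**2 - 5.896e-5 * t**3
    pct = 100.0 * record.get("dissolved_oxygen") / do_sat
    return p.get("slope", 1.0) * pct + p.get("intercept", 0.0)


TRANSFORMS: dict[str, Callable[[PhyschemRecord, Mapping, str], float]] = {
    "linear": _t_linear,
    "power": _t_power,
    "exp10": _t_exp10,
    "piecewise_linear": _t_piecewise_linear,
    "ph_dinius": _t_ph_dinius,
    "temperature_difference": _t_temperature_difference,
    "oxygen_saturation": _t_oxygen_saturation,
}


@dataclass(frozen=True)
class SubindexSpec:
    """One parameter's subindex: weight plus a named transform."""

    parameter: str
    weight: float
    transform: str
    params: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ConfigError(f"weight for {self.parameter!r} must be > 0")
        if self.transform not in TRANSFORMS:
            raise ConfigError(
                f"unknown transform {self.transform!r} for {self.parameter!r}; "
                f"known: {sorted(TRANSFORMS)}"
            )


def compute_subindex(record: PhyschemRecord, spec: SubindexSpec) -> float:
    """Apply a subindex transform and clamp the result to [0, 100]."""
    raw = TRANSFORMS[spec.transform](record, spec.params, spec.parameter)
    return min(100.0, max(0.0, float(raw)))


@dataclass(frozen=True)
class WQIResult:
    site_id: str
    season: str
    wqi: float
    subindices: Mapping[str, float]
    general_category: str
    use_categories: Mapping[str, str]


def compute_wqi(
    record: PhyschemRecord,
    specs: Sequence[SubindexSpec] | None = None,
    *,
    renormalize: bool = False,
    use_table: "UseCategoryTable | None" = None,
) -> WQIResult:
    """Weighted geometric product of subindices for one record.

    Weights must sum to 1 (within 1e-6) unless ``renormalize`` is set, in
    which case they are rescaled (logged) — intended for incomplete field
    records scored with a reduced spec set.  Any zero subindex annihilates
    the product.
    """
    if specs is None:
        specs = DEFAULT_SUBINDEX_SPECS
    if not specs:
        raise ConfigError("no subindex specs")
    seen = [s.parameter for s in specs]
    if len(set(seen)) != len(seen):
        raise ConfigError(f"duplicate subindex parameter in specs: {seen}")
    wsum = sum(s.weight for s in specs)
    if abs(wsum - 1.0) > WEIGHT_SUM_TOL:
        if not renormalize:
            raise ConfigError(
                f"subindex weights sum to {wsum:.6f}, not 1; pass "
                "renormalize=True to rescale a reduced spec set"
            )
        logger.info("renormalizing %d weights (sum %.6f -> 1)", len(specs), wsum)
    subindices = {s.parameter: compute_subindex(record, s) for s in specs}
    log_wqi = 0.0
    zero = False
    for s in specs:
        i = subindices[s.parameter]
        if i == 0.0:
            zero = True
            break
        log_wqi += (s.weight / wsum) * math.log(i)
    wqi = 0.0 if zero else min(100.0, math.exp(log_wqi))
    table = use_table if use_table is not None else DEFAULT_USE_TABLE
    return WQIResult(
        site_id=record.site_id,
        season=record.season,
        wqi=wqi,
        subindices=subindices,
        general_category=classify_general(wqi),
        use_categories={use: classify_by_use(wqi, use, table) for use in table.uses},
    )


# ---------------------------------------------------------------------------
# Category scales
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UseCategoryTable:
    """Per-use ordered category scales with inclusive lower bounds on WQI.

    ``aliases`` maps alternative display spellings onto canonical class
    names (the published prose uses two spellings for the agriculture
    "minor purification" class).
    """

    scales: Mapping[str, Sequence[tuple[str, float]]]
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for use, classes in self.scales.items():
            bounds = [b for _, b in classes]
            if any(b2 >= b1 for b1, b2 in zip(bounds, bounds[1:])):
                raise ConfigError(f"bounds for use {use!r} not strictly decreasing")
            if bounds[-1] != 0:
                raise ConfigError(f"last bound for use {use!r} must be 0")

    @property
    def uses(self) -> tuple[str, ...]:
        return tuple(self.scales)

    def canonical(self, category: str) -> str:
        return self.aliases.get(category, category)


def _classify(wqi: float, classes: Sequence[tuple[str, float]]) -> str:
    if not 0 <= wqi <= 100 or not math.isfinite(wqi):
        raise ValueError(f"WQI must be in [0, 100], got {wqi!r}")
    for name, bound in classes:
        if wqi >= bound:
            return name
    raise AssertionError("unreachable")


#: General-scale classes.  The Mild contamination / Acceptable boundary at 70
#: is fixed by the published seasonal means (68.48 -> Mild contamination,
#: 70.83 -> Acceptable); the remaining cutoffs are conventional.
DEFAULT_GENERAL_SCHEME: tuple[tuple[str, float], ...] = (
    ("Excellent", 90.0),
    ("Acceptable", 70.0),
    ("Mild contamination", 50.0),
    ("Contaminated", 25.0),
    ("Heavily contaminated", 0.0),
)


def classify_general(
    wqi: float, scheme: Sequence[tuple[str, float]] = DEFAULT_GENERAL_SCHEME
) -> str:
    """General (use-independent) quality class of a WQI score."""
    return _classify(wqi, scheme)


def classify_by_use(wqi: float, use: str, table: "UseCategoryTable | None" = None) -> str:
    """Quality class of a WQI score on one water-use scale."""
    if table is None:
        table = DEFAULT_USE_TABLE
    if use not in table.scales:
        raise KeyError(f"unknown water use {use!r}; known: {sorted(table.scales)}")
    return _classify(wqi, table.scales[use])


#: Use scales for the two uses analyzed (agriculture, public water supply).
#: Cutoffs are a reconstruction of the Dinius use grading consistent with
#: the published category ordering; override via config for other gradings.
DEFAULT_USE_TABLE = UseCategoryTable(
    scales={
        "agriculture": (
            ("Purification Not Necessary", 90.0),
            ("Minor Purification for Crops Requiring High-Quality Water", 72.0),
            ("No Treatment Necessary for Most Crops", 40.0),
            ("Extensive Treatment for Most Crops", 20.0),
            ("Unacceptable for Irrigation", 0.0),
        ),
        "public_water_supply": (
            ("Purification Not Necessary", 90.0),
            ("Minor Purification Required", 80.0),
            ("Necessary Treatment Becoming More Extensive", 50.0),
            ("Doubtful for Consumption", 25.0),
            ("Unacceptable for Consumption", 0.0),
        ),
    },
    aliases={
        "Regular and Minor Purification for Crops Requiring High-Water Quality":
            "Minor Purification for Crops Requiring High-Quality Water",
    },
)


# ---------------------------------------------------------------------------
# Default subindex configuration (Dinius 1987 reconstruction)
# ---------------------------------------------------------------------------

def _coliform_spec(parameter: str, weight: float, a: float, b: float) -> SubindexSpec:
    return SubindexSpec(
        parameter, weight, "power", {"a": a, "b": b, "floor": COLIFORM_FLOOR}
    )


DEFAULT_SUBINDEX_SPECS: tuple[SubindexSpec, ...] = (
    SubindexSpec(
        "dissolved_oxygen", 0.109, "oxygen_saturation",
        {"slope": 0.82, "intercept": 10.56},
    ),
    SubindexSpec("bod5", 0.097, "power", {"a": 108.0, "b": -0.3494, "floor": 1.0}),
    _coliform_spec("total_coliforms", 0.090, 136.0, -0.1311),
    _coliform_spec("fecal_coliforms", 0.116, 106.0, -0.1286),
    SubindexSpec(
        "pH", 0.077, "ph_dinius",
        {"acid_a": 0.6803, "acid_b": 0.1856, "alk_a": 3.65, "alk_b": -0.2216},
    ),
    SubindexSpec("alkalinity", 0.063, "power", {"a": 110.0, "b": -0.1342, "floor": 1.0}),
    SubindexSpec("hardness", 0.065, "power", {"a": 552.0, "b": -0.4488, "floor": 1.0}),
    SubindexSpec("chlorides", 0.074, "power", {"a": 391.0, "b": -0.3480, "floor": 1.0}),
    SubindexSpec("conductivity", 0.079, "power", {"a": 506.0, "b": -0.3315, "floor": 1.0}),
    SubindexSpec(
        "water_temperature", 0.077, "temperature_difference",
        {"a": 2.004, "b": -0.0382},
    ),
    SubindexSpec("color", 0.063, "power", {"a": 127.0, "b": -0.2394, "floor": 1.0}),
    SubindexSpec("nitrates", 0.090, "power", {"a": 125.0, "b": -0.2718, "floor": 1.0}),
)


# ---------------------------------------------------------------------------
# Config / CSV I/O
# ---------------------------------------------------------------------------

def load_subindex_specs(path: str | Path) -> tuple[SubindexSpec, ...]:
    """Load subindex specs from a YAML file.

    Expected layout::

        subindices:
          - parameter: bod5
            weight: 0.097
            transform: power
            params: {a: 108.0, b: -0.3494}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    try:
        raw = cfg["subindices"]
    except (TypeError, KeyError):
        raise ConfigError(f"{path}: expected a top-level 'subindices' list") from None
    return tuple(
        SubindexSpec(
            d["parameter"], float(d["weight"]), d["transform"], d.get("params", {})
        )
        for d in raw
    )


def load_physchem(path: str | Path) -> list[PhyschemRecord]:
    """Read a physchem CSV (one row per site x season, PhyschemRecord columns)."""
    df = pd.read_csv(path)
    missing = set(("site_id", "season") + PARAMETERS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        PhyschemRecord(
            site_id=str(row.site_id), season=str(row.season),
            **{p: float(getattr(row, p)) for p in PARAMETERS},
        )
        for row in df.itertuples()
    ]


def results_frame(results: Sequence[WQIResult]) -> pd.DataFrame:
    """Tabular view of WQI results for CSV export."""
    rows = []
    for r in results:
        row = {
            "site_id": r.site_id, "season": r.season, "wqi": r.wqi,
            "general_category": r.general_category,
        }
        for use, cat in r.use_categories.items():
            row[f"category_{use}"] = cat
        rows.append(row)
    return pd.DataFrame(rows)
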