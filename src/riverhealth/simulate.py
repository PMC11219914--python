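"""Synthetic study-condition generator: sites along an organic-pollution gradient.

Everything the analysis pipeline consumes can be generated here without any
download: macroinvertebrate communities whose family occurrence is linked to
tolerance scores through a logistic response to a pollution gradient,
physicochemical records with monotone responses to the same gradient (plus a
sub-basin offset emulating the hard/salty endogenous-river contrast),
reflectance raster pairs built so that the buffer-mean NDVI at each site is
a known target, and regression tables drawn from the published extension
equation.  All generators are pure functions of (scenario, seed): a fixed
seed reproduces outputs exactly.

The generative model is deliberately minimal — it encodes just enough
mechanism (occurrence probability p = logistic(k(s_f/10 - g)) for a family
with tolerance score s_f at gradient g in [0, 1]) for the pipeline's
qualitative behaviour (BMWP and WQI decline as pollution rises) to be a
testable consequence rather than an assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from shapely import contains_xy

from .bmwp import FamilyToleranceTable, MacroinvertebrateSample
from .extension import QUALIFIERS, PublishedModel, PUBLISHED_MODEL, RegressionDataset
from .ndvi import (
    DEFAULT_BUFFER_HALF_WIDTH_M,
    DEFAULT_BUFFER_LENGTH_M,
    SitePoint,
    build_buffer,
)
from .raster import RasterBand
from .wqi import PhyschemRecord

__all__ = [
    "GradientScenario",
    "SyntheticDataset",
    "DEFAULT_FAMILY_POOL",
    "generate_communities",
    "generate_physchem",
    "generate_rasters",
    "generate_regression_table",
    "generate_dataset",
]

# stream ids for per-generator rng derivation from the master seed
_STREAM_COMMUNITIES = 0
_STREAM_PHYSCHEM = 1
_STREAM_RASTERS = 2
_STREAM_REGRESSION = 3

#: Illustrative 30-family pool spanning the tolerance range uniformly
#: (three families per score); replace via the scenario for real tables.
DEFAULT_FAMILY_POOL = FamilyToleranceTable(
    {
        "Tubificidae": 1, "Psychodidae": 1, "Syrphidae": 1,
        "Chironomidae": 2, "Culicidae": 2, "Muscidae": 2,
        "Hirudinidae": 3, "Physidae": 3, "Valvatidae": 3,
        "Caenidae": 4, "Coenagrionidae": 4, "Dytiscidae": 4,
        "Baetidae": 5, "Hydropsychidae": 5, "Simuliidae": 5,
        "Aeshnidae": 6, "Corixidae": 6, "Tipulidae": 6,
        "Elmidae": 7, "Gomphidae": 7, "Hydroptilidae": 7,
        "Ephemerellidae": 8, "Philopotamidae": 8, "Psephenidae": 8,
        "Glossosomatidae": 9, "Leptophlebiidae": 9, "Sericostomatidae": 9,
        "Chloroperlidae": 10, "Heptageniidae": 10, "Perlidae": 10,
    }
)

#: Monotone physicochemical response to the gradient:
#: parameter -> (baseline at g=0, slope per unit g, noise sd, clip range).
#: Directions: dissolved oxygen falls with pollution; BOD5, coliforms,
#: color, nutrients and ionic load rise; water warms relative to air.
DEFAULT_PHYSCHEM_RESPONSE: dict[str, tuple[float, float, float, tuple[float, float]]] = {
    "atmospheric_temperature": (24.0, 0.0, 0.8, (0.0, 45.0)),
    "water_temperature": (24.0, 6.0, 0.5, (0.0, 40.0)),
    "dissolved_oxygen": (8.5, -6.0, 0.25, (0.0, 15.0)),
    "pH": (7.8, 0.4, 0.08, (6.0, 9.0)),
    "conductivity": (400.0, 800.0, 30.0, (0.0, np.inf)),
    "nitrates": (1.0, 8.0, 0.2, (0.0, np.inf)),
    "alkalinity": (120.0, 80.0, 8.0, (0.0, np.inf)),
    "hardness": (150.0, 150.0, 10.0, (0.0, np.inf)),
    "chlorides": (30.0, 120.0, 5.0, (0.0, np.inf)),
    "color": (5.0, 60.0, 2.0, (0.0, np.inf)),
    "bod5": (1.5, 18.0, 0.4, (0.0, np.inf)),
    "total_coliforms": (100.0, 20000.0, 50.0, (0.0, np.inf)),
    "fecal_coliforms": (20.0, 8000.0, 20.0, (0.0, np.inf)),
}

#: Extra ionic load of the endogenous ("salty") sub-basin, added to the
#: baseline regardless of the gradient.
DEFAULT_SALTY_OFFSETS = {
    "conductivity": 1500.0,
    "chlorides": 200.0,
    "hardness": 250.0,
    "alkalinity": 100.0,
}

#: Qualifier sampling ranges for regression tables (uniform draws, units as
#: in the physchem records; nutrients mg/L).
QUALIFIER_RANGES: dict[str, tuple[float, float]] = {
    "salinity": (0.1, 2.0),
    "conductivity": (200.0, 3000.0),
    "Cl": (10.0, 300.0),
    "NO2": (0.0, 0.3),
    "NH3": (0.0, 1.0),
    "color": (1.0, 60.0),
    "NO3": (0.5, 10.0),
    "N_total": (0.5, 10.0),
    "pH": (6.5, 8.5),
    "hardness": (50.0, 500.0),
    "SO4": (20.0, 400.0),
}


@dataclass(frozen=True)
class RasterSpec:
    """Geometry and vegetation link of the synthetic reflectance rasters."""

    pixel_size: float = 10.0
    site_spacing: float = 600.0
    red_reflectance: float = 0.2
    background_ndvi: float = 0.12
    #: linear vegetation link: target buffer NDVI = intercept + slope * g
    ndvi_intercept: float = 0.65
    ndvi_slope: float = -0.45
    #: additive seasonal shift of the target (rainy season greener)
    season_offset: Mapping[str, float] = field(
        default_factory=lambda: {"dry": 0.0, "rainy": 0.10}
    )
    crs: str = "synthetic-utm-meters"


@dataclass(frozen=True)
class GradientScenario:
    """Parameters of the synthetic pollution gradient.

    ``gradient`` holds one pollution intensity g in [0, 1] per site
    (default: evenly spaced 0..1).  ``occurrence_steepness`` is the logistic
    slope k of the family-occurrence model.  Setting every noise sd to zero
    (``without_noise``) makes physchem records a deterministic function of g.
    """

    n_sites: int = 12
    seasons: tuple[str, ...] = ("dry", "rainy")
    gradient: tuple[float, ...] | None = None
    family_pool: FamilyToleranceTable = DEFAULT_FAMILY_POOL
    occurrence_steepness: float = 10.0
    physchem_response: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_PHYSCHEM_RESPONSE)
    )
    salty_offsets: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SALTY_OFFSETS)
    )
    raster_spec: RasterSpec = RasterSpec()
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if not self.seasons or set(self.seasons) - {"dry", "rainy"}:
            raise ValueError("seasons must be a non-empty subset of {dry, rainy}")
        if self.occurrence_steepness <= 0:
            raise ValueError("occurrence_steepness must be > 0")
        if len(self.family_pool) == 0:
            raise ValueError("family pool is empty")
        g = self.gradient
        if g is None:
            g = tuple(np.linspace(0.0, 1.0, self.n_sites))
        g = tuple(float(v) for v in g)
        if len(g) != self.n_sites:
            raise ValueError("gradient length must equal n_sites")
        if any(not 0 <= v <= 1 for v in g):
            raise ValueError("gradient values must be in [0, 1]")
        for name, (_, _, sd, _) in self.physchem_response.items():
            if sd < 0:
                raise ValueError(f"noise sd for {name!r} must be >= 0")
        object.__setattr__(self, "gradient", g)

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1:02d}" for i in range(self.n_sites))

    def sub_basin(self, i: int) -> str:
        """First half of the sites drain the salty sub-basin."""
        return "salado" if i < self.n_sites // 2 else "grande"

    def without_noise(self) -> "GradientScenario":
        response = {
            name: (b, s, 0.0, clip)
            for name, (b, s, sd, clip) in self.physchem_response.items()
        }
        return replace(self, physchem_response=response)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


def occurrence_probability(
    tolerance_score: float, g: float, steepness: float
) -> float:
    """P(family present | gradient g); 0.5 exactly when s/10 equals g."""
    return float(expit(steepness * (tolerance_score / 10.0 - g)))


def generate_communities(scenario: GradientScenario) -> list[MacroinvertebrateSample]:
    """Draw per-site, per-season family occurrence from the logistic model."""
    rng = scenario.rng(_STREAM_COMMUNITIES)
    k = scenario.occurrence_steepness
    families = sorted(scenario.family_pool.entries.items())
    samples = []
    for i, g in enumerate(scenario.gradient):
        for season in scenario.seasons:
            records = []
            for family, score in families:
                p = occurrence_probability(score, g, k)
                if rng.random() < p:
                    abundance = int(rng.poisson(5)) + 1
                    records.append((family.capitalize(), abundance))
            samples.append(
                MacroinvertebrateSample(scenario.site_ids[i], season, records)
            )
    return samples


def expected_bmwp(scenario: GradientScenario, g: float) -> float:
    """Closed-form expectation of the BMWP score at gradient g."""
    k = scenario.occurrence_steepness
    return sum(
        s * occurrence_probability(s, g, k)
        for s in scenario.family_pool.entries.values()
    )


def generate_physchem(scenario: GradientScenario) -> list[PhyschemRecord]:
    """Linear-in-gradient physicochemistry with clipped Gaussian noise."""
    rng = scenario.rng(_STREAM_PHYSCHEM)
    records = []
    for i, g in enumerate(scenario.gradient):
        basin = scenario.sub_basin(i)
        for season in scenario.seasons:
            values = {}
            for name, (baseline, slope, sd, (lo, hi)) in scenario.physchem_response.items():
                value = baseline + slope * g
                if basin == "salado":
                    value += scenario.salty_offsets.get(name, 0.0)
                if sd > 0:
                    value += rng.normal(0.0, sd)
                values[name] = float(np.clip(value, lo, hi))
            records.append(
                PhyschemRecord(site_id=scenario.site_ids[i], season=season, **values)
            )
    return records


def _site_points(scenario: GradientScenario) -> list[SitePoint]:
    spec = scenario.raster_spec
    # sites on a west-east line, buffers pointing north (upstream), spaced
    # widely enough that no two buffers overlap
    return [
        SitePoint(
            site_id=scenario.site_ids[i],
            x=500.0 + i * spec.site_spacing,
            y=500.0,
            upstream_azimuth=0.0,
            crs=spec.crs,
        )
        for i in range(scenario.n_sites)
    ]


def generate_rasters(
    scenario: GradientScenario,
    targets: Mapping[tuple[str, str], float] | None = None,
) -> tuple[dict[str, tuple[RasterBand, RasterBand]], list[SitePoint]]:
    """NIR/red band pairs whose buffer-mean NDVI equals known targets.

    Returns ``(bands_by_season, site_points)`` where each band pair is built
    so the pixels inside every site's riparian buffer carry exactly that
    site's target NDVI (default: the scenario's linear vegetation link to
    the gradient plus a seasonal offset).  The construction inverts the NDVI
    formula pixel-wise — NIR = R (1 + t)/(1 - t) — so the round trip through
    the analysis module recovers the target to floating-point precision.
    """
    spec = scenario.raster_spec
    sites = _site_points(scenario)
    margin = DEFAULT_BUFFER_LENGTH_M + DEFAULT_BUFFER_HALF_WIDTH_M
    xmax = max(s.x for s in sites) + margin
    ymax = max(s.y for s in sites) + margin + DEFAULT_BUFFER_LENGTH_M
    ncols = int(np.ceil(xmax / spec.pixel_size)) + 1
    nrows = int(np.ceil(ymax / spec.pixel_size)) + 1
    origin = (0.0, nrows * spec.pixel_size)
    template = RasterBand(
        np.zeros((nrows, ncols)), origin, spec.pixel_size, spec.crs, nodata=-9999.0
    )
    xs, ys = template.pixel_centers()
    out: dict[str, tuple[RasterBand, RasterBand]] = {}
    for season in scenario.seasons:
        ndvi_field = np.full((nrows, ncols), spec.background_ndvi)
        for i, (site, g) in enumerate(zip(sites, scenario.gradient)):
            if targets is not None:
                t = targets[(site.site_id, season)]
            else:
                t = (
                    spec.ndvi_intercept
                    + spec.ndvi_slope * g
                    + spec.season_offset.get(season, 0.0)
                )
            if not -0.99 <= t <= 0.99:
                raise ValueError(
                    f"target NDVI {t} for {site.site_id}/{season} not in (-0.99, 0.99)"
                )
            buffer = build_buffer(site)
            poly = buffer.as_shapely()
            xmin, ymin, xmax_b, ymax_b = poly.bounds
            bxmin, bymin, bxmax, bymax = template.bounds
            if xmin < bxmin or ymin < bymin or xmax_b > bxmax or ymax_b > bymax:
                raise ValueError(
                    f"buffer of {site.site_id} extends beyond the raster"
                )
            inside = contains_xy(poly, xs.ravel(), ys.ravel()).reshape(xs.shape)
            ndvi_field[inside] = t
        red = np.full((nrows, ncols), spec.red_reflectance)
        nir = red * (1.0 + ndvi_field) / (1.0 - ndvi_field)
        out[season] = (template.with_values(nir), template.with_values(red))
    return out, sites


def generate_regression_table(
    scenario: GradientScenario,
    model: PublishedModel = PUBLISHED_MODEL,
    noise_sd: float = 0.0,
) -> RegressionDataset:
    """Qualifier table with BMWP_obs drawn from the extension equation.

    Predictors are uniform over realistic field ranges; the response is the
    model's linear prediction plus Gaussian noise (floored at 0, since BMWP
    is a non-negative sum — with the default ranges the floor is inactive at
    moderate noise).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = scenario.rng(_STREAM_REGRESSION)
    n = scenario.n_sites
    columns = {
        name: rng.uniform(lo, hi, size=n) for name, (lo, hi) in QUALIFIER_RANGES.items()
    }
    predictors = pd.DataFrame(columns, columns=list(QUALIFIERS))
    obs = np.full(n, model.intercept)
    for name, coef in model.coefficients.items():
        obs = obs + coef * predictors[name].to_numpy()
    if noise_sd > 0:
        obs = obs + rng.normal(0.0, noise_sd, size=n)
    obs = np.maximum(obs, 0.0)
    return RegressionDataset(scenario.site_ids, obs, predictors)


@dataclass(frozen=True)
class SyntheticDataset:
    """Everything the pipeline consumes, plus the generating truth."""

    samples: list[MacroinvertebrateSample]
    physchem: list[PhyschemRecord]
    rasters: dict[str, tuple[RasterBand, RasterBand]]
    sites: list[SitePoint]
    regression: RegressionDataset
    truth: dict


def generate_dataset(
    scenario: GradientScenario, regression_noise_sd: float = 0.0
) -> SyntheticDataset:
    """One coherent dataset keyed by the same site ids and seasons throughout."""
    rasters, sites = generate_rasters(scenario)
    spec = scenario.raster_spec
    truth = {
        "seed": scenario.seed,
        "gradient": {s: g for s, g in zip(scenario.site_ids, scenario.gradient)},
        "sub_basin": {
            s: scenario.sub_basin(i) for i, s in enumerate(scenario.site_ids)
        },
        "occurrence_steepness": scenario.occurrence_steepness,
        "ndvi_targets": {
            f"{site}/{season}": spec.ndvi_intercept
            + spec.ndvi_slope * g
            + spec.season_offset.get(season, 0.0)
            for site, g in zip(scenario.site_ids, scenario.gradient)
            for season in scenario.seasons
        },
        "regression_model": {
            "intercept": PUBLISHED_MODEL.intercept,
            **dict(PUBLISHED_MODEL.coefficients),
        },
    }
    return SyntheticDataset(
        samples=generate_communities(scenario),
        physchem=generate_physchem(scenario),
        rasters=rasters,
        sites=sites,
        regression=generate_regression_table(scenario, noise_sd=regression_noise_sd),
        truth=truth,
    )
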