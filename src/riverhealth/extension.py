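"""Geographic-extension validation of the BMWP index.

A biotic index calibrated on one set of sites can be extended to new sites
by (1) regressing observed BMWP on the physicochemical qualifiers used in
the calibration, (2) predicting BMWP_calc at every site from the fitted (or
a published) equation, and (3) checking that the new sites fall inside the
95% band of the calculated-vs-observed regression.  Sites outside the band
are flagged as departures from the calibrated relationship.

The published extension equation for these rivers is

    BMWP_calc = 92.697 - 5.982 * N_total + 260.634 * NO2

with nutrient concentrations in mg/L.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "QUALIFIERS",
    "RegressionDataset",
    "FittedModel",
    "PublishedModel",
    "PUBLISHED_MODEL",
    "ValidationVerdict",
    "fit_extension_model",
    "predict_bmwp",
    "band_and_flag",
]

#: Water-quality variables admitted as regression qualifiers.
QUALIFIERS = (
    "salinity", "conductivity", "Cl", "NO2", "NH3", "color",
    "NO3", "N_total", "pH", "hardness", "SO4",
)


@dataclass(frozen=True)
class RegressionDataset:
    """Observed BMWP with named qualifier predictors, one row per site."""

    site_ids: tuple[str, ...]
    bmwp_obs: np.ndarray
    predictors: pd.DataFrame

    def __post_init__(self) -> None:
        obs = np.asarray(self.bmwp_obs, dtype=float)
        if len(self.site_ids) != len(obs) or len(obs) != len(self.predictors):
            raise ValueError("site_ids, bmwp_obs and predictors disagree in length")
        if len(obs) < 2:
            raise ValueError("need at least 2 rows")
        if (obs < 0).any():
            raise ValueError("bmwp_obs must be non-negative")
        unknown = set(self.predictors.columns) - set(QUALIFIERS)
        if unknown:
            raise ValueError(f"unknown qualifier column(s): {sorted(unknown)}")
        if self.predictors.isna().any().any():
            raise ValueError("missing values in predictors")
        object.__setattr__(self, "bmwp_obs", obs)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegressionDataset":
        cols = [c for c in df.columns if c in QUALIFIERS]
        return cls(
            tuple(str(s) for s in df["site_id"]),
            df["bmwp_obs"].to_numpy(dtype=float),
            df[cols].astype(float).reset_index(drop=True),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegressionDataset":
        df = pd.read_csv(path)
        missing = {"site_id", "bmwp_obs"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        return cls.from_frame(df)


@dataclass(frozen=True)
class FittedModel:
    intercept: float
    coefficients: Mapping[str, float]
    r_squared: float
    residual_df: int
    selected_variables: tuple[str, ...]
    selection_trace: tuple[str, ...] = ()

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.coefficients)


@dataclass(frozen=True)
class PublishedModel:
    """The published extension equation, immutable."""

    intercept: float = 92.697
    coefficients: Mapping[str, float] = field(
        default_factory=lambda: {"N_total": -5.982, "NO2": 260.634}
    )

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.coefficients)


PUBLISHED_MODEL = PublishedModel()

# A coefficient below this fraction of the response scale is treated as an
# exact zero during backward elimination when its p-value is undefined
# (perfect-fit residuals make OLS standard errors 0/0).
_NEGLIGIBLE_REL = 1e-8


def _ols(y: np.ndarray, X: pd.DataFrame):
    design = sm.add_constant(X, has_constant="add")
    return sm.OLS(y, design).fit()


def fit_extension_model(
    data: RegressionDataset,
    selection: str = "backward",
    alpha: float = 0.05,
    variables: Sequence[str] | None = None,
) -> FittedModel:
    """OLS of observed BMWP on qualifier variables.

    ``selection='backward'`` starts from all candidate variables and
    repeatedly drops the least significant one with p > alpha;
    ``selection='none'`` fits the given ``variables`` (default: all columns)
    as-is.  Reports R^2, residual df and a drop trace.
    """
    if selection not in ("none", "backward"):
        raise ValueError(f"selection must be 'none' or 'backward', got {selection!r}")
    cols = list(variables) if variables is not None else list(data.predictors.columns)
    missing = set(cols) - set(data.predictors.columns)
    if missing:
        raise ValueError(f"requested variable(s) not in dataset: {sorted(missing)}")
    y = data.bmwp_obs
    n = len(y)
    if n < len(cols) + 2 and selection == "backward":
        # still allow exactly-determined fits in 'none' mode; selection needs slack
        if n < len(cols) + 1:
            raise ValueError(
                f"{n} rows cannot support backward selection over {len(cols)} candidates"
            )
    if n < len(cols) + 1:
        raise ValueError(f"{n} rows cannot fit {len(cols)} predictors plus intercept")
    yscale = max(float(np.abs(y).max()), 1.0)
    trace: list[str] = []
    while True:
        X = data.predictors[cols]
        rank = np.linalg.matrix_rank(sm.add_constant(X, has_constant="add").to_numpy())
        if cols and rank < len(cols) + 1:
            raise ValueError(
                f"design matrix is rank deficient over columns {cols}; "
                "remove collinear qualifiers"
            )
        res = _ols(y, X)
        if selection == "none" or not cols:
            break
        pvals = res.pvalues.drop("const")
        coefs = res.params.drop("const")
        # undefined p-values (zero-residual fits) count as droppable only
        # for coefficients that are numerically zero
        adj = pvals.copy()
        for name in adj.index:
            if np.isnan(adj[name]):
                adj[name] = 1.0 if abs(coefs[name]) < _NEGLIGIBLE_REL * yscale else 0.0
        worst = adj.idxmax()
        if adj[worst] <= alpha:
            break
        cols.remove(worst)
        trace.append(f"dropped {worst} (p={pvals[worst]:.4g})")
    params = res.params
    r2 = float(res.rsquared)
    if math.isnan(r2):  # constant response: define R^2 as 0
        r2 = 0.0
    return FittedModel(
        intercept=float(params["const"]),
        coefficients={c: float(params[c]) for c in cols},
        r_squared=min(max(r2, 0.0), 1.0),
        residual_df=int(res.df_resid),
        selected_variables=tuple(cols),
        selection_trace=tuple(trace),
    )


def predict_bmwp(
    model: FittedModel | PublishedModel, predictors: Mapping[str, float]
) -> float:
    """Linear evaluation of a fitted or published model; never clamped."""
    value = model.intercept
    for name, coef in model.coefficients.items():
        if name not in predictors:
            raise KeyError(f"model requires variable {name!r}, not provided")
        value += coef * float(predictors[name])
    if value < 0:
        logger.info("predicted BMWP is negative (%.3f); reported as-is", value)
    return float(value)


@dataclass(frozen=True)
class ValidationVerdict:
    """Per-site band membership of the calc-vs-obs regression."""

    site_ids: tuple[str, ...]
    bmwp_obs: np.ndarray
    bmwp_calc: np.ndarray
    inside_band: np.ndarray
    band: str
    level: float
    lower: np.ndarray
    upper: np.ndarray

    @property
    def outside_sites(self) -> tuple[str, ...]:
        return tuple(
            s for s, ok in zip(self.site_ids, self.inside_band) if not ok
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_ids,
                "bmwp_obs": self.bmwp_obs,
                "bmwp_calc": self.bmwp_calc,
                "band_lower": self.lower,
                "band_upper": self.upper,
                "inside_band": self.inside_band,
            }
        )


def band_and_flag(
    pairs: Sequence[tuple[float, float]],
    level: float = 0.95,
    band: str = "confidence",
    site_ids: Sequence[str] | None = None,
    test_pairs: Sequence[tuple[float, float]] | None = None,
) -> ValidationVerdict:
    """Fit calc ~ obs and flag pairs by membership in the pointwise band.

    ``band='confidence'`` uses the mean-response band; ``band='prediction'``
    the (wider) new-observation band.  Both use the t quantile at the fit's
    residual df, evaluated at each observed value.  When ``test_pairs`` is
    given the band is still fitted on ``pairs`` but the verdict covers the
    test pairs (e.g. calibration sites fit the band, new monitoring sites
    are judged against it).
    """
    if band not in ("confidence", "prediction"):
        raise ValueError(f"band must be 'confidence' or 'prediction', got {band!r}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    pairs = [(float(o), float(c)) for o, c in pairs]
    if len(pairs) < 3:
        raise ValueError("need at least 3 (obs, calc) pairs")
    obs = np.array([o for o, _ in pairs])
    calc = np.array([c for _, c in pairs])
    if np.ptp(obs) == 0:
        raise ValueError("observed BMWP has zero variance; band is undefined")
    X = sm.add_constant(pd.DataFrame({"obs": obs}))
    res = sm.OLS(calc, X).fit()
    if test_pairs is not None:
        obs = np.array([float(o) for o, _ in test_pairs])
        calc = np.array([float(c) for _, c in test_pairs])
        X = sm.add_constant(pd.DataFrame({"obs": obs}), has_constant="add")
    if site_ids is None:
        site_ids = tuple(f"site_{i}" for i in range(len(obs)))
    pred = res.get_prediction(X)
    frame = pred.summary_frame(alpha=1.0 - level)
    if band == "confidence":
        lower = frame["mean_ci_lower"].to_numpy()
        upper = frame["mean_ci_upper"].to_numpy()
    else:
        lower = frame["obs_ci_lower"].to_numpy()
        upper = frame["obs_ci_upper"].to_numpy()
    # numerical slack so an exactly colinear point (zero-residual fit, band
    # width at float-noise scale) is never flagged by rounding error
    eps = 1e-9 * max(1.0, float(np.abs(calc).max()))
    inside = (calc >= lower - eps) & (calc <= upper + eps)
    return ValidationVerdict(
        site_ids=tuple(str(s) for s in site_ids),
        bmwp_obs=obs,
        bmwp_calc=calc,
        inside_band=inside,
        band=band,
        level=level,
        lower=lower,
        upper=upper,
    )
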