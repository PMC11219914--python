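"""Index integration: site x season matrix assembly, PCA, group comparisons.

The three indices (BMWP, WQI, NDVI) are treated as attributes of each
site x season observation.  Ordination uses PCA on the Pearson correlation
matrix (i.e. columns standardized to zero mean and unit variance), so the
three indices contribute on equal footing despite their different scales.
Group differences (between sub-basins or between seasons) are reported with
per-group Shapiro-Wilk normality, Levene homogeneity of variance, and a
one-way ANOVA; the diagnostic tests are reported alongside the ANOVA, never
used to gate it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bmwp import BMWPResult
from .ndvi import NDVIResult
from .wqi import WQIResult

logger = logging.getLogger(__name__)

__all__ = [
    "SiteIndexMatrix",
    "PCAResult",
    "GroupComparison",
    "assemble_matrix",
    "run_pca",
    "compare_groups",
]

INDEX_COLUMNS = ("bmwp", "wqi", "ndvi")

#: Season suffixes used in row labels (mirrors the dry-season/rainy-season
#: labelling of the ordination output).
SEASON_SUFFIX = {"dry": "DS", "rainy": "RS"}


@dataclass(frozen=True)
class SiteIndexMatrix:
    """Rows keyed by (site_id, season); columns bmwp, wqi, ndvi."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = set(INDEX_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"matrix missing column(s) {sorted(missing)}")
        if df[list(INDEX_COLUMNS)].isna().any().any():
            raise ValueError("matrix has missing cells")
        object.__setattr__(self, "data", df)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def labels(self) -> list[str]:
        return [
            f"{site} {SEASON_SUFFIX.get(season, season)}"
            for site, season in zip(self.data["site_id"], self.data["season"])
        ]

    def season_averaged(self) -> "SiteIndexMatrix":
        """Collapse seasons to one mean row per site."""
        df = (
            self.data.groupby("site_id", as_index=False)[list(INDEX_COLUMNS)]
            .mean()
        )
        df["season"] = "mean"
        return SiteIndexMatrix(df[["site_id", "season", *INDEX_COLUMNS]])


def assemble_matrix(
    bmwp: Sequence[BMWPResult],
    wqi: Sequence[WQIResult],
    ndvi: Sequence[NDVIResult],
) -> SiteIndexMatrix:
    """Inner-join the three index outputs on (site_id, season).

    Rows missing any index are excluded and logged.
    """
    def frame(results, column, attr):
        return pd.DataFrame(
            {
                "site_id": [r.site_id for r in results],
                "season": [r.season for r in results],
                column: [getattr(r, attr) for r in results],
            }
        )

    b = frame(bmwp, "bmwp", "score")
    w = frame(wqi, "wqi", "wqi")
    n = frame(ndvi, "ndvi", "mean_ndvi")
    merged = b.merge(w, on=["site_id", "season"]).merge(n, on=["site_id", "season"])
    all_keys = set()
    for df in (b, w, n):
        all_keys |= set(zip(df["site_id"], df["season"]))
    kept = set(zip(merged["site_id"], merged["season"]))
    dropped = all_keys - kept
    if dropped:
        logger.warning(
            "assemble_matrix: %d site x season rows missing an index dropped: %s",
            len(dropped), sorted(dropped),
        )
    if merged.empty:
        raise ValueError("no (site_id, season) keys shared by all three indices")
    return SiteIndexMatrix(merged)


@dataclass(frozen=True)
class PCAResult:
    """Correlation-matrix PCA: loadings, scores, explained-variance shares."""

    loadings: pd.DataFrame           # variables x components
    scores: pd.DataFrame             # rows x components
    variance_fraction: np.ndarray    # per component, sums to 1
    eigenvalues: np.ndarray

    @property
    def cumulative_fraction(self) -> np.ndarray:
        return np.cumsum(self.variance_fraction)


def run_pca(matrix: SiteIndexMatrix | pd.DataFrame) -> PCAResult:
    """PCA of the index matrix via the Pearson correlation matrix.

    Columns are standardized (ddof=1); the correlation matrix is
    eigendecomposed; scores are the standardized data projected on the
    eigenvectors.  Each loading vector is oriented so its largest-magnitude
    element is positive, for reproducible output.
    """
    df = matrix.data if isinstance(matrix, SiteIndexMatrix) else matrix
    cols = [c for c in df.columns if c in INDEX_COLUMNS] or [
        c for c in df.columns if np.issubdtype(df[c].dtype, np.number)
    ]
    X = df[cols].to_numpy(dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError(f"PCA needs >= 3 rows, got {n}")
    sd = X.std(axis=0, ddof=1)
    for name, s in zip(cols, sd):
        if s == 0:
            raise ValueError(f"column {name!r} has zero variance; cannot correlation-scale")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-|.| element of each loading vector positive
    for j in range(p):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    comp_names = [f"PC{i + 1}" for i in range(p)]
    labels = (
        matrix.labels if isinstance(matrix, SiteIndexMatrix) else list(df.index)
    )
    return PCAResult(
        loadings=pd.DataFrame(eigvecs, index=cols, columns=comp_names),
        scores=pd.DataFrame(Z @ eigvecs, index=labels, columns=comp_names),
        variance_fraction=eigvals / eigvals.sum(),
        eigenvalues=eigvals,
    )


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA with its diagnostic tests, purely descriptive."""

    grouping: str
    normality_p: Mapping[str, float]       # Shapiro-Wilk per group
    variance_homogeneity_p: float          # Levene (median-centered)
    anova_f: float
    anova_p: float
    group_means: Mapping[str, float]


def compare_groups(
    values: Sequence[float],
    groups: Sequence[str],
    grouping: str = "group",
) -> GroupComparison:
    """Shapiro-Wilk per group, Levene on medians, and one-way ANOVA."""
    values = np.asarray(values, dtype=float)
    if len(values) != len(groups):
        raise ValueError("values and groups disagree in length")
    by_group: dict[str, np.ndarray] = {}
    for label in dict.fromkeys(groups):
        by_group[str(label)] = values[np.asarray(groups) == label]
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups")
    for label, v in by_group.items():
        if len(v) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 observations")
    normality = {}
    for label, v in by_group.items():
        if np.ptp(v) == 0:
            normality[label] = float("nan")  # Shapiro undefined on constants
        else:
            normality[label] = float(stats.shapiro(v).pvalue)
    samples = list(by_group.values())
    if all(np.ptp(v) == 0 for v in samples):
        levene_p = float("nan")
    else:
        levene_p = float(stats.levene(*samples, center="median").pvalue)
    f, p = stats.f_oneway(*samples)
    if np.isnan(f):  # identical values everywhere: no between-group variance
        f, p = 0.0, 1.0
    return GroupComparison(
        grouping=grouping,
        normality_p=normality,
        variance_homogeneity_p=levene_p,
        anova_f=float(f),
        anova_p=float(p),
        group_means={label: float(v.mean()) for label, v in by_group.items()},
    )
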