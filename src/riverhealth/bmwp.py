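"""BMWP biotic-index scoring from macroinvertebrate family records.

The Biological Monitoring Working Party (BMWP) index is a presence-based
biotic index: each macroinvertebrate family carries an integer bioindication
(tolerance) score from 1 (highly tolerant of organic pollution) to 10 (highly
sensitive), and the score of a site is the sum of the scores of the distinct
families present.  Higher scores indicate cleaner water.  Scores are mapped
to ordered water-quality categories (Excellent ... Extremely polluted)
through a configurable :class:`CategoryScheme`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FamilyToleranceTable",
    "MacroinvertebrateSample",
    "BMWPResult",
    "CategoryScheme",
    "DEFAULT_BMWP_SCHEME",
    "load_tolerance_table",
    "score_bmwp",
    "classify_bmwp",
    "seasonal_mean",
    "tabulate_category_percentages",
]

SEASONS = ("dry", "rainy")


class ValidationError(ValueError):
    """Raised when an input table or record violates its contract."""


def _normalize_family(name: str) -> str:
    return str(name).strip().casefold()


@dataclass(frozen=True)
class FamilyToleranceTable:
    """Family name -> integer bioindication score in [1, 10].

    Names are matched after whitespace trimming and case-folding; no fuzzy
    matching is attempted (a silently misassigned family is worse than an
    unknown-family warning).
    """

    entries: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValidationError("tolerance table is empty")
        normalized: dict[str, int] = {}
        for name, score in self.entries.items():
            key = _normalize_family(name)
            if not key:
                raise ValidationError("empty family name in tolerance table")
            if key in normalized:
                raise ValidationError(
                    f"duplicate family after normalization: {name!r}"
                )
            if not float(score).is_integer():
                raise ValidationError(
                    f"non-integer tolerance score for {name!r}: {score!r}"
                )
            score = int(score)
            if not 1 <= score <= 10:
                raise ValidationError(
                    f"tolerance score for {name!r} out of [1, 10]: {score}"
                )
            normalized[key] = score
        object.__setattr__(self, "entries", normalized)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, family: str) -> bool:
        return _normalize_family(family) in self.entries

    def score_of(self, family: str) -> int | None:
        return self.entries.get(_normalize_family(family))

    @property
    def max_score(self) -> int:
        """Sum over every family in the table (attained iff all present)."""
        return sum(self.entries.values())


@dataclass(frozen=True)
class MacroinvertebrateSample:
    """One site x season record of families present.

    Abundances are optional and carried only for provenance: BMWP is a
    presence/absence index, so they never affect the score.  Duplicate family
    entries are permitted on input and collapse to one occurrence.
    """

    site_id: str
    season: str
    records: Sequence[tuple[str, int | None]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not str(self.site_id).strip():
            raise ValidationError("site_id must be non-empty")
        if self.season not in SEASONS:
            raise ValidationError(
                f"season must be one of {SEASONS}, got {self.season!r}"
            )
        recs = []
        for item in self.records:
            if isinstance(item, str):
                item = (item, None)
            family, abundance = item
            if abundance is not None and int(abundance) <= 0:
                raise ValidationError(
                    f"abundance must be positive, got {abundance!r} for {family!r}"
                )
            recs.append((str(family), None if abundance is None else int(abundance)))
        object.__setattr__(self, "records", tuple(recs))

    @property
    def families(self) -> tuple[str, ...]:
        """Distinct normalized family names, input order preserved."""
        seen: dict[str, None] = {}
        for family, _ in self.records:
            seen.setdefault(_normalize_family(family), None)
        return tuple(seen)


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered water-quality classes with inclusive lower bounds.

    ``classes`` is a descending list of ``(name, lower_bound)``; the first
    entry is the best class and the last bound must be 0 so the scheme covers
    [0, inf).  A score exactly on a bound belongs to the higher class.
    """

    classes: Sequence[tuple[str, float]]

    def __post_init__(self) -> None:
        classes = tuple((str(n), float(b)) for n, b in self.classes)
        if not classes:
            raise ValidationError("category scheme is empty")
        names = [n for n, _ in classes]
        if len(set(names)) != len(names):
            raise ValidationError("category names must be unique")
        bounds = [b for _, b in classes]
        if any(b2 >= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValidationError("category bounds must be strictly decreasing")
        if bounds[-1] != 0:
            raise ValidationError("last category lower bound must be 0")
        object.__setattr__(self, "classes", classes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.classes)

    @property
    def worst(self) -> str:
        return self.classes[-1][0]

    def classify(self, score: float) -> str:
        if not math.isfinite(score) or score < 0:
            raise ValidationError(f"score must be finite and >= 0, got {score!r}")
        for name, bound in self.classes:
            if score >= bound:
                return name
        raise AssertionError("unreachable: scheme covers [0, inf)")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "CategoryScheme":
        items = sorted(mapping.items(), key=lambda kv: -float(kv[1]))
        return cls(tuple(items))


#: Six-class scheme consistent with every published BMWP value-category pair
#: for these rivers (e.g. 28.3 -> Poor, 83.8 -> Good, 104.88 -> Very Good).
#: The calibrated cutoffs themselves are not published, so this is a
#: constrained reconstruction and is config-overridable.
DEFAULT_BMWP_SCHEME = CategoryScheme(
    (
        ("Excellent", 121),
        ("Very Good", 101),
        ("Good", 61),
        ("Fair", 36),
        ("Poor", 16),
        ("Extremely polluted", 0),
    )
)


@dataclass(frozen=True)
class BMWPResult:
    site_id: str
    season: str
    score: float
    n_families_scored: int
    unknown_families: tuple[str, ...]
    category: str


def load_tolerance_table(path: str | Path) -> FamilyToleranceTable:
    """Read a ``family,score`` CSV into a validated tolerance table."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"family", "score"} - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: missing column(s) {sorted(missing)}; need family,score"
        )
    entries: dict[str, int] = {}
    for row in df.itertuples(index=True):
        family = str(row.family)
        key = _normalize_family(family)
        if key in entries:
            raise ValidationError(
                f"{path} row {row.Index}: duplicate family {family!r} "
                "after case/whitespace normalization"
            )
        try:
            score = float(row.score)
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path} row {row.Index}: non-numeric score {row.score!r}"
            ) from None
        if not score.is_integer() or not 1 <= score <= 10:
            raise ValidationError(
                f"{path} row {row.Index}: score {row.score!r} for {family!r} "
                "must be an integer in [1, 10]"
            )
        entries[family] = int(score)
    return FamilyToleranceTable(entries)


def score_bmwp(
    sample: MacroinvertebrateSample, table: FamilyToleranceTable
) -> BMWPResult:
    """Sum the tolerance scores of the distinct known families in a sample.

    Families absent from the table contribute 0, are listed in
    ``unknown_families`` and logged at warning level, so citizen-collected
    lists with extra taxa still score.
    """
    score = 0
    n_scored = 0
    unknown: list[str] = []
    for family in sample.families:
        s = table.score_of(family)
        if s is None:
            unknown.append(family)
        else:
            score += s
            n_scored += 1
    if unknown:
        logger.warning(
            "site %s (%s): %d unknown families skipped: %s",
            sample.site_id, sample.season, len(unknown), ", ".join(unknown),
        )
    return BMWPResult(
        site_id=sample.site_id,
        season=sample.season,
        score=float(score),
        n_families_scored=n_scored,
        unknown_families=tuple(unknown),
        category=DEFAULT_BMWP_SCHEME.classify(score),
    )


def classify_bmwp(
    score: float, scheme: CategoryScheme = DEFAULT_BMWP_SCHEME
) -> str:
    """Map a BMWP score to its water-quality category name."""
    return scheme.classify(score)


def seasonal_mean(
    results: Sequence[BMWPResult | float],
    scheme: CategoryScheme = DEFAULT_BMWP_SCHEME,
) -> tuple[float, float, str]:
    """Mean score over seasons/replicates with its standard error.

    Returns ``(mean, standard_error, category_of_mean)``.  The category is
    computed on the mean, matching how per-site values are reported as the
    average of dry and rainy seasons.  SE is the sample standard deviation
    over sqrt(n), reported as 0 for a single observation.
    """
    values = [r.score if isinstance(r, BMWPResult) else float(r) for r in results]
    if not values:
        raise ValidationError("seasonal_mean needs at least one result")
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        se = 0.0
    else:
        var = sum((v - mean) ** 2 for v in values) / (n - 1)
        se = math.sqrt(var / n)
    return mean, se, scheme.classify(mean)


def tabulate_category_percentages(
    assignments: Mapping[str, str],
    scheme: CategoryScheme,
    rounding_mode: str = "round-half-up",
    decimals: int = 2,
) -> dict[str, float]:
    """Percentage of sites in each category, at a fixed decimal precision.

    ``rounding_mode`` is either ``round-half-up`` or ``truncate``; published
    tabulations use both conventions (5/18 prints as 27.77 only under
    truncation), so the mode is explicit.  Categories with no sites are
    reported as 0 so the table is exhaustive over the scheme.
    """
    if not assignments:
        raise ValidationError("no site assignments to tabulate")
    if rounding_mode not in ("round-half-up", "truncate"):
        raise ValidationError(f"unknown rounding mode {rounding_mode!r}")
    valid = set(scheme.names)
    counts = {name: 0 for name in scheme.names}
    for site, category in assignments.items():
        if category not in valid:
            raise ValidationError(
                f"site {site!r} assigned to {category!r}, not in scheme {sorted(valid)}"
            )
        counts[category] += 1
    total = len(assignments)
    factor = 10 ** decimals
    out: dict[str, float] = {}
    for name, count in counts.items():
        pct = 100.0 * count / total
        if rounding_mode == "truncate":
            out[name] = math.floor(pct * factor) / factor
        else:
            out[name] = math.floor(pct * factor + 0.5) / factor
    return out


def score_samples(
    samples: Iterable[MacroinvertebrateSample],
    table: FamilyToleranceTable,
    scheme: CategoryScheme = DEFAULT_BMWP_SCHEME,
) -> list[BMWPResult]:
    """Score a batch of samples under one table and scheme."""
    out = []
    for sample in samples:
        r = score_bmwp(sample, table)
        if scheme is not DEFAULT_BMWP_SCHEME:
            r = BMWPResult(
                r.site_id, r.season, r.score, r.n_families_scored,
                r.unknown_families, scheme.classify(r.score),
            )
        out.append(r)
    return out


def load_samples(path: str | Path) -> list[MacroinvertebrateSample]:
    """Read a samples CSV (site_id, season, family[, abundance]) into samples."""
    df = pd.read_csv(path)
    missing = {"site_id", "season", "family"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing column(s) {sorted(missing)}")
    has_abund = "abundance" in df.columns
    samples = []
    for (site, season), grp in df.groupby(["site_id", "season"], sort=False):
        records = []
        for row in grp.itertuples():
            abund = None
            if has_abund and pd.notna(row.abundance):
                abund = int(row.abundance)
            records.append((str(row.family), abund))
        samples.append(MacroinvertebrateSample(str(site), str(season), records))
    return samples


def results_frame(results: Sequence[BMWPResult]) -> pd.DataFrame:
    """Tabular view of scoring results for CSV export."""
    return pd.DataFrame(
        {
            "site_id": [r.site_id for r in results],
            "season": [r.season for r in results],
            "score": [r.score for r in results],
            "n_families": [r.n_families_scored for r in results],
            "category": [r.category for r in results],
            "unknown_families": [";".join(r.unknown_families) for r in results],
        }
    )
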