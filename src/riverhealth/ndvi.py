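"""Riparian-buffer NDVI: vegetation index rasters and zonal means.

NDVI = (NIR - R) / (NIR + R) from near-infrared and red reflectance, bounded
in [-1, 1]; higher values indicate denser/more vigorous vegetation.  The
riparian condition at a monitoring site is summarized as the mean NDVI over
an oriented rectangular buffer extending a fixed length upstream of the site
and a fixed half-width to each side of the upstream axis (defaults 200 m
upstream x 120 m per side, i.e. a 200 x 240 m rectangle).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import Polygon

from .raster import GeometryError, RasterBand, looks_geographic, require_aligned

logger = logging.getLogger(__name__)

__all__ = [
    "SitePoint",
    "BufferPolygon",
    "NDVIResult",
    "compute_ndvi",
    "build_buffer",
    "zonal_mean_ndvi",
    "DEFAULT_BUFFER_LENGTH_M",
    "DEFAULT_BUFFER_HALF_WIDTH_M",
]

DEFAULT_BUFFER_LENGTH_M = 200.0
#: Width on *each* side of the upstream axis (total width is twice this).
DEFAULT_BUFFER_HALF_WIDTH_M = 120.0


@dataclass(frozen=True)
class SitePoint:
    """A monitoring site in a projected, meter-unit CRS.

    ``upstream_azimuth`` is the direction toward upstream, in degrees
    clockwise from grid north.
    """

    site_id: str
    x: float
    y: float
    upstream_azimuth: float
    crs: str = "local-meters"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"site {self.site_id}: coordinates must be finite")
        if not 0 <= self.upstream_azimuth < 360:
            raise ValueError(
                f"site {self.site_id}: azimuth must be in [0, 360), "
                f"got {self.upstream_azimuth}"
            )


@dataclass(frozen=True)
class BufferPolygon:
    """Oriented rectangular riparian buffer."""

    corners: tuple[tuple[float, float], ...]
    length_m: float
    half_width_m: float

    @property
    def area(self) -> float:
        return self.length_m * 2.0 * self.half_width_m

    def as_shapely(self) -> Polygon:
        return Polygon(self.corners)


@dataclass(frozen=True)
class NDVIResult:
    site_id: str
    season: str
    mean_ndvi: float
    n_pixels: int


def compute_ndvi(nir: RasterBand, red: RasterBand) -> RasterBand:
    """Per-pixel (NIR - R)/(NIR + R) on two aligned reflectance bands.

    Pixels where either input is missing, or where NIR + R = 0, become
    nodata in the output.
    """
    require_aligned(nir, red)
    valid = nir.mask() & red.mask()
    n = nir.values
    r = red.values
    denom = n + r
    ok = valid & (denom != 0)
    out = np.full(nir.shape, np.nan)
    out[ok] = (n[ok] - r[ok]) / denom[ok]
    n_zero = int(np.count_nonzero(valid & ~ok))
    if n_zero:
        logger.debug("compute_ndvi: %d pixels with NIR+R = 0 set to nodata", n_zero)
    return RasterBand(out, nir.origin, nir.pixel_size, nir.crs, nodata=np.nan)


def build_buffer(
    site: SitePoint,
    length_m: float = DEFAULT_BUFFER_LENGTH_M,
    half_width_m: float = DEFAULT_BUFFER_HALF_WIDTH_M,
) -> BufferPolygon:
    """Oriented rectangle extending upstream of a site.

    The rectangle runs ``length_m`` from the site along the upstream azimuth
    and ``half_width_m`` to each side of that axis.  Requires projected,
    meter-unit coordinates.
    """
    if looks_geographic(site.x, site.y, site.crs):
        raise GeometryError(
            f"site {site.site_id}: coordinates look geographic (degrees); "
            "reproject sites to a projected CRS in meters before buffering"
        )
    if length_m <= 0 or half_width_m <= 0:
        raise ValueError("buffer length and half-width must be > 0")
    az = math.radians(site.upstream_azimuth)
    # unit vector toward upstream (azimuth clockwise from grid north)
    ux, uy = math.sin(az), math.cos(az)
    # unit vector to the right of the upstream axis
    rx, ry = uy, -ux
    x, y = site.x, site.y
    corners = (
        (x - half_width_m * rx, y - half_width_m * ry),
        (x + half_width_m * rx, y + half_width_m * ry),
        (x + half_width_m * rx + length_m * ux, y + half_width_m * ry + length_m * uy),
        (x - half_width_m * rx + length_m * ux, y - half_width_m * ry + length_m * uy),
    )
    return BufferPolygon(corners, float(length_m), float(half_width_m))


def zonal_mean_ndvi(
    ndvi: RasterBand,
    buffer: BufferPolygon,
    site_id: str = "",
    season: str = "dry",
) -> NDVIResult:
    """Mean NDVI over valid pixels whose centers fall inside the buffer."""
    poly = buffer.as_shapely()
    xs, ys = ndvi.pixel_centers()
    inside = contains_xy(poly, xs.ravel(), ys.ravel()).reshape(ndvi.shape)
    if not inside.any():
        raise GeometryError(
            f"buffer does not intersect the raster (raster bounds {ndvi.bounds})"
        )
    use = inside & ndvi.mask()
    n_nodata = int(np.count_nonzero(inside & ~ndvi.mask()))
    if n_nodata:
        logger.info("zonal_mean_ndvi: %d nodata pixels inside buffer excluded", n_nodata)
    if not use.any():
        raise GeometryError("all pixels inside the buffer are nodata")
    values = ndvi.values[use]
    mean = float(values.mean())
    if not -1.0 <= mean <= 1.0:
        raise ValueError(f"mean NDVI {mean} outside [-1, 1]; inputs are not reflectances")
    return NDVIResult(site_id=site_id, season=season,
                      mean_ndvi=mean, n_pixels=int(use.sum()))


def summarize_sites(
    nir: RasterBand,
    red: RasterBand,
    sites: Sequence[SitePoint],
    season: str,
    length_m: float = DEFAULT_BUFFER_LENGTH_M,
    half_width_m: float = DEFAULT_BUFFER_HALF_WIDTH_M,
) -> list[NDVIResult]:
    """NDVI buffer means for many sites against one band pair."""
    ndvi = compute_ndvi(nir, red)
    return [
        zonal_mean_ndvi(ndvi, build_buffer(s, length_m, half_width_m), s.site_id, season)
        for s in sites
    ]


def load_sites(path: str | Path) -> list[SitePoint]:
    """Read site points from CSV (site_id, x, y, azimuth[, crs])."""
    df = pd.read_csv(path)
    missing = {"site_id", "x", "y", "azimuth"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    has_crs = "crs" in df.columns
    return [
        SitePoint(
            str(row.site_id), float(row.x), float(row.y), float(row.azimuth),
            str(row.crs) if has_crs else "local-meters",
        )
        for row in df.itertuples()
    ]


def results_frame(results: Sequence[NDVIResult]) -> pd.DataFrame:
    """Tabular view of zonal NDVI results for CSV export."""
    return pd.DataFrame(
        {
            "site_id": [r.site_id for r in results],
            "season": [r.season for r in results],
            "mean_ndvi": [r.mean_ndvi for r in results],
            "n_pixels": [r.n_pixels for r in results],
        }
    )
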