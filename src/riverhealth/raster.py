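"""Minimal single-band georeferenced raster container with text I/O.

A :class:`RasterBand` is a 2-D grid of values plus a north-up affine
georeference (origin of the top-left corner, square pixel size in meters)
and a coordinate-reference-system label.  Only projected, meter-unit CRSs
are supported; rasters are read and written as ESRI ASCII grids (``.asc``),
a plain-text interchange format understood by all GIS software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["RasterBand", "read_ascii_grid", "write_ascii_grid"]

NODATA_DEFAULT = -9999.0


class GeometryError(ValueError):
    """Raised for misaligned or invalid raster geometry."""


@dataclass(frozen=True)
class RasterBand:
    """One raster band on a north-up, square-pixel, meter-unit grid.

    ``values`` has shape (nrows, ncols); row 0 is the northernmost row.
    ``origin`` is the (x, y) of the top-left *corner* of the top-left pixel.
    ``nodata`` marks missing pixels (NaN is also treated as missing).
    """

    values: np.ndarray
    origin: tuple[float, float]
    pixel_size: float
    crs: str = "local-meters"
    nodata: float = NODATA_DEFAULT

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise GeometryError(f"raster values must be a non-empty 2-D grid, got shape {arr.shape}")
        if self.pixel_size <= 0:
            raise GeometryError(f"pixel size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        return (x0, y0 - nrows * self.pixel_size, x0 + ncols * self.pixel_size, y0)

    def geometry_tuple(self) -> tuple:
        return (self.shape, self.origin, self.pixel_size, self.crs)

    def aligned_with(self, other: "RasterBand") -> bool:
        return self.geometry_tuple() == other.geometry_tuple()

    def mask(self) -> np.ndarray:
        """Boolean grid of valid (non-nodata, finite) pixels."""
        v = self.values
        return np.isfinite(v) & (v != self.nodata)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate grids of pixel centers, each shape (nrows, ncols)."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.pixel_size
        ys = y0 - (np.arange(nrows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def with_values(self, values: np.ndarray) -> "RasterBand":
        """Same georeference, new values."""
        return RasterBand(values, self.origin, self.pixel_size, self.crs, self.nodata)


def require_aligned(a: RasterBand, b: RasterBand) -> None:
    if not a.aligned_with(b):
        raise GeometryError(
            "raster bands are not aligned: "
            f"{a.geometry_tuple()} vs {b.geometry_tuple()}"
        )


def write_ascii_grid(band: RasterBand, path: str | Path) -> None:
    """Write a band as an ESRI ASCII grid with a CRS comment sidecar line."""
    nrows, ncols = band.shape
    x0, y0 = band.origin
    yll = y0 - nrows * band.pixel_size
    values = np.where(band.mask(), band.values, band.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {x0!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {band.pixel_size!r}\n")
        fh.write(f"NODATA_value {band.nodata!r}\n")
        np.savetxt(fh, values, fmt="%.10g")
    Path(str(path) + ".crs").write_text(band.crs + "\n")


def read_ascii_grid(path: str | Path) -> RasterBand:
    """Read an ESRI ASCII grid (with optional ``.crs`` sidecar)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"):
                header[key] = float(value)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    for required in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if required not in header:
            raise GeometryError(f"{path}: missing ASCII-grid header field {required}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise GeometryError(
            f"{path}: grid shape {values.shape} does not match header ({nrows}, {ncols})"
        )
    origin = (header["xllcorner"], header["yllcorner"] + nrows * header["cellsize"])
    crs_path = Path(str(path) + ".crs")
    crs = crs_path.read_text().strip() if crs_path.exists() else "local-meters"
    return RasterBand(
        values, origin, header["cellsize"], crs,
        header.get("nodata_value", NODATA_DEFAULT),
    )


def looks_geographic(x: float, y: float, crs: str) -> bool:
    """Guard against lat/lon coordinates passed where meters are required.

    The CRS label is the authority; a bare (unlabelled) CRS falls back on a
    coordinate-magnitude heuristic, since real projected coordinates in
    meters rarely sit inside the +-180/+-90 degree box.
    """
    label = crs.lower()
    if any(tag in label for tag in ("4326", "wgs84", "latlon", "lonlat", "geographic", "degree")):
        return True
    if not label.strip():
        return abs(x) <= 180 and abs(y) <= 90
    return False
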