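"""Raster data model, alignment rules, geodesic helpers and file I/O.

Every spatial layer in the pipeline is a :class:`RasterGrid`: a single-band
2D array on a regular geographic (lon/lat, degrees) grid with cell-center
registration, row 0 = northernmost row, and an explicit validity mask.
Layers entering one computation must be *aligned* (identical shape,
transform and CRS); misalignment is always an error, never an implicit
resample.

Rasters are persisted as ESRI ASCII grids (``.asc``) — a plain-text,
georeferenced single-band format readable by every GIS. Floats are written
with 17 significant digits so a write/read round trip is bit-exact.

Areas are computed per cell on the sphere (radius 6371 km) instead of
reprojecting to an equal-area CRS: a cell spanning latitudes [phi1, phi2]
and dlambda degrees of longitude has area R^2 * dlambda_rad *
(sin phi2 - sin phi1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "Transform",
    "RasterGrid",
    "AlignmentError",
    "EnvStack",
    "read_raster",
    "write_raster",
    "cell_areas",
    "great_circle_km",
    "initial_bearing_deg",
]


class AlignmentError(ValueError):
    """Raised when layers with different shape/transform/CRS are combined."""


class Transform(NamedTuple):
    """Georeference of a north-up regular grid.

    ``west``/``north`` are the outer edges of the top-left cell; ``cell_size``
    is the square cell edge in degrees.
    """

    west: float
    north: float
    cell_size: float

    def cell_center(self, row, col):
        """Lon/lat of the center of cell (row, col); accepts arrays."""
        lon = self.west + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.north - (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat

    def index_of(self, lon, lat):
        """Row/col of the cell containing a point (half-open edges).

        Offsets are snapped to 1e-9 cells before flooring so points lying
        exactly on a cell edge land deterministically in the cell whose
        leading edge they touch, immune to floating-point wobble.
        """
        dx = (np.asarray(lon) - self.west) / self.cell_size
        dy = (self.north - np.asarray(lat)) / self.cell_size
        col = np.floor(np.round(dx, 9)).astype(int)
        row = np.floor(np.round(dy, 9)).astype(int)
        return row, col


@dataclass
class RasterGrid:
    """One georeferenced 2D layer with a nodata mask.

    Parameters
    ----------
    values : ndarray (n_rows, n_cols)
        Cell values; content under invalid cells is unspecified.
    transform : Transform
    mask : bool ndarray, same shape
        True where the cell is valid.
    crs : str
        Coordinate reference identifier; the pipeline operates in EPSG:4326.
    """

    values: np.ndarray
    transform: Transform
    mask: np.ndarray = None  # type: ignore[assignment]
    crs: str = "EPSG:4326"

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("RasterGrid values must be 2D")
        if self.mask is None:
            self.mask = np.isfinite(self.values.astype(float))
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        self.transform = Transform(*self.transform)

    @property
    def shape(self):
        return self.values.shape

    def copy_with(self, values, mask=None):
        """New grid on the same georeference."""
        return RasterGrid(
            np.asarray(values),
            self.transform,
            self.mask.copy() if mask is None else np.asarray(mask, dtype=bool),
            self.crs,
        )

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.crs == other.crs
            and np.allclose(self.transform, other.transform, rtol=0, atol=1e-12)
        )

    def require_aligned(self, other: "RasterGrid", what: str = "layer"):
        if not self.aligned_with(other):
            raise AlignmentError(
                f"{what}: shape/transform/crs mismatch "
                f"({self.shape}, {tuple(self.transform)}, {self.crs}) vs "
                f"({other.shape}, {tuple(other.transform)}, {other.crs})"
            )

    def cell_centers(self):
        """(lon, lat) 2D arrays of every cell center."""
        rows = np.arange(self.shape[0])
        cols = np.arange(self.shape[1])
        cgrid, rgrid = np.meshgrid(cols, rows)
        return self.transform.cell_center(rgrid, cgrid)

    def center_lats(self):
        """Latitude of each row's cell centers (1D, length n_rows)."""
        return self.transform.north - (np.arange(self.shape[0]) + 0.5) * self.transform.cell_size

    def center_lons(self):
        return self.transform.west + (np.arange(self.shape[1]) + 0.5) * self.transform.cell_size


def require_all_aligned(grids, what="layers"):
    grids = list(grids)
    for g in grids[1:]:
        grids[0].require_aligned(g, what)


def combined_valid_mask(grids) -> np.ndarray:
    """Conservative nodata propagation: valid only where every input is."""
    grids = list(grids)
    require_all_aligned(grids)
    m = grids[0].mask.copy()
    for g in grids[1:]:
        m &= g.mask
    return m


@dataclass
class EnvStack:
    """Named collection of aligned environmental layers for one scenario."""

    layers: dict[str, RasterGrid]
    scenario: str = "current"

    def __post_init__(self):
        names = list(self.layers)
        if len(set(names)) != len(names):
            raise ValueError("duplicate layer names")
        require_all_aligned(self.layers.values(), "EnvStack")

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def names(self):
        return list(self.layers)

    @property
    def template(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def valid_mask(self) -> np.ndarray:
        return combined_valid_mask(self.layers.values())

    def subset(self, names) -> "EnvStack":
        return EnvStack({n: self.layers[n] for n in names}, self.scenario)

    def table(self, rows, cols) -> np.ndarray:
        """(n_points, n_layers) matrix of layer values at given cells."""
        return np.column_stack([g.values[rows, cols] for g in self.layers.values()])


# ---------------------------------------------------------------------------
# I/O — ESRI ASCII grid
# ---------------------------------------------------------------------------

_NODATA = -99999.0


def write_raster(grid: RasterGrid, path) -> None:
    """Write a grid as an ESRI ASCII grid (plain text, bit-exact floats)."""
    path = Path(path)
    n_rows, n_cols = grid.shape
    t = grid.transform
    south = t.north - n_rows * t.cell_size
    vals = grid.values.astype(float).copy()
    vals[~grid.mask] = _NODATA
    with open(path, "w") as fh:
        fh.write(f"ncols {n_cols}\n")
        fh.write(f"nrows {n_rows}\n")
        fh.write(f"xllcorner {t.west!r}\n")
        fh.write(f"yllcorner {south!r}\n")
        fh.write(f"cellsize {t.cell_size!r}\n")
        fh.write(f"NODATA_value {_NODATA!r}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.17g}" for v in row))
            fh.write("\n")


def read_raster(path) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_raster` (or any GIS)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header: dict[str, float] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: not a georeferenced ASCII grid (missing {req})")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = np.array(rows, dtype=float)
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data block {values.shape} != header ({n_rows},{n_cols})")
    nodata = header.get("nodata_value", _NODATA)
    mask = values != nodata
    transform = Transform(
        header["xllcorner"],
        header["yllcorner"] + n_rows * header["cellsize"],
        header["cellsize"],
    )
    return RasterGrid(values, transform, mask)


# ---------------------------------------------------------------------------
# Geodesy
# ---------------------------------------------------------------------------

def cell_areas(grid: RasterGrid) -> RasterGrid:
    """Per-cell surface area (km^2) on a sphere of radius 6371 km.

    Constant along rows; decreases with |latitude|. Rejects grids whose
    coordinates cannot be geographic degrees.
    """
    t = grid.transform
    n_rows, n_cols = grid.shape
    south = t.north - n_rows * t.cell_size
    if t.north > 90.000001 or south < -90.000001 or grid.crs.upper() not in (
        "EPSG:4326", "WGS84", "CRS:84",
    ):
        raise ValueError(
            "cell_areas requires a geographic (degree) grid within [-90, 90] "
            "latitude; supply explicit areas for projected grids"
        )
    lat_top = t.north - np.arange(n_rows) * t.cell_size
    lat_bot = lat_top - t.cell_size
    dlam = math.radians(t.cell_size)
    band = EARTH_RADIUS_KM**2 * dlam * (np.sin(np.radians(lat_top)) - np.sin(np.radians(lat_bot)))
    values = np.repeat(band[:, None], n_cols, axis=1)
    return RasterGrid(values, t, np.ones_like(values, dtype=bool), grid.crs)


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine great-circle distance in km; accepts arrays."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing from point 1 to point 2, clockwise from
    north, in [0, 360)."""
    lam1, phi1, lam2, phi2 = (math.radians(v) for v in (lon1, lat1, lon2, lat2))
    dlon = lam2 - lam1
    y = math.sin(dlon) * math.cos(phi2)
    x = math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(phi2) * math.cos(dlon)
    return math.degrees(math.atan2(y, x)) % 360.0
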