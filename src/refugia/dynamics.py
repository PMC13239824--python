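"""Per-species range summaries and shift geometry.

Given a species' current and future binary range maps, this module reports
the quantities a climate-impact assessment tabulates per species: suitable
area (km^2, geodesic cell areas), the percentage change in climatically
suitable habitat

    CSH = (Area_future - Area_current) / Area_current * 100,

area-weighted mean elevation, geodesic range centroids (3D unit-vector
averaging), great-circle shift distance, initial bearing, quadrant
direction bin (NE/SE/SW/NW, half-open at the cardinal bearings), and a
1-standard-deviation deviational ellipse of the range on a local planar
approximation.

A species contracting past CSH <= -50% is flagged as drastic shrinkage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grid import EARTH_RADIUS_KM, RasterGrid, great_circle_km, initial_bearing_deg

__all__ = [
    "RangeSummary",
    "CentroidShift",
    "Ellipse",
    "range_area",
    "csh",
    "csh_class",
    "mean_elevation",
    "range_centroid",
    "centroid_shift",
    "deviational_ellipse",
    "DRASTIC_CSH_PCT",
]

# contraction at or beyond -50% counts as drastic range shrinkage
DRASTIC_CSH_PCT = -50.0


@dataclass
class RangeSummary:
    species_id: str
    area_current_km2: float
    area_future_km2: float
    csh_pct: float | None
    csh_class: str  # expansion | contraction | stable | undefined
    drastic: bool
    mean_elev_current_m: float | None
    mean_elev_future_m: float | None
    elev_shift_m: float | None
    elev_shift_pct: float | None


@dataclass
class CentroidShift:
    centroid_current: tuple[float, float] | None  # (lon, lat)
    centroid_future: tuple[float, float] | None
    distance_km: float | None
    bearing_deg: float | None
    direction_bin: str | None  # NE | SE | SW | NW


@dataclass
class Ellipse:
    center_lon: float
    center_lat: float
    semi_major_km: float
    semi_minor_km: float
    azimuth_deg: float  # major-axis direction, clockwise from north, [0, 180)


def _presence(binary: RasterGrid) -> np.ndarray:
    return (binary.values > 0) & binary.mask


def range_area(binary: RasterGrid, areas: RasterGrid) -> float:
    """Total area (km^2) of presence cells."""
    binary.require_aligned(areas, "range_area")
    return float(areas.values[_presence(binary)].sum())


def csh(area_current: float, area_future: float) -> float | None:
    """Percentage change in climatically suitable habitat; None if the
    current range is empty (undefined)."""
    if area_current <= 0:
        return None
    return (area_future - area_current) / area_current * 100.0


def csh_class(value: float | None) -> str:
    if value is None:
        return "undefined"
    if value > 0:
        return "expansion"
    if value < 0:
        return "contraction"
    return "stable"


def mean_elevation(binary: RasterGrid, dem: RasterGrid, areas: RasterGrid) -> float | None:
    """Area-weighted mean DEM over presence cells; None for empty ranges."""
    binary.require_aligned(dem, "mean_elevation")
    binary.require_aligned(areas, "mean_elevation")
    sel = _presence(binary) & dem.mask
    if not sel.any():
        return None
    w = areas.values[sel]
    return float(np.average(dem.values[sel], weights=w))


def range_centroid(
    binary: RasterGrid,
    areas: RasterGrid,
    weights: RasterGrid | None = None,
) -> tuple[float, float]:
    """Area-weighted geodesic centroid (lon, lat) of presence cells.

    Cell-center unit vectors are averaged in 3D and renormalized to the
    sphere, so the result is meaningful across meridians. Pass a
    suitability grid as ``weights`` for a suitability-weighted centroid.
    """
    binary.require_aligned(areas, "range_centroid")
    sel = _presence(binary)
    if not sel.any():
        raise ValueError("empty range has no centroid")
    lon, lat = binary.cell_centers()
    w = areas.values[sel]
    if weights is not None:
        binary.require_aligned(weights, "range_centroid weights")
        w = w * weights.values[sel]
    lam = np.radians(lon[sel])
    phi = np.radians(lat[sel])
    x = np.sum(w * np.cos(phi) * np.cos(lam))
    y = np.sum(w * np.cos(phi) * np.sin(lam))
    z = np.sum(w * np.sin(phi))
    norm = math.sqrt(x * x + y * y + z * z)
    if norm < 1e-12 * w.sum():
        raise ValueError("degenerate (near-antipodal) range: zero resultant vector")
    return (
        math.degrees(math.atan2(y, x)),
        math.degrees(math.asin(np.clip(z / norm, -1, 1))),
    )


_BINS = ((0.0, 90.0, "NE"), (90.0, 180.0, "SE"), (180.0, 270.0, "SW"), (270.0, 360.0, "NW"))


def direction_bin(bearing_deg: float) -> str:
    """Quadrant bin with half-open edges: NE=[0,90), SE=[90,180), ..."""
    b = bearing_deg % 360.0
    for lo, hi, name in _BINS:
        if lo <= b < hi:
            return name
    return "NE"  # b == 360.0 after fp wobble


def centroid_shift(c1: tuple[float, float], c2: tuple[float, float]) -> CentroidShift:
    """Great-circle distance, initial bearing and quadrant bin from centroid
    c1 (lon, lat) to c2. Identical points: distance 0, bearing undefined."""
    d = float(great_circle_km(c1[0], c1[1], c2[0], c2[1]))
    if d < 1e-9:
        return CentroidShift(c1, c2, 0.0, None, None)
    b = initial_bearing_deg(c1[0], c1[1], c2[0], c2[1])
    return CentroidShift(c1, c2, d, b, direction_bin(b))


def summarize_range(
    species_id: str,
    binary_current: RasterGrid,
    binary_future: RasterGrid,
    dem: RasterGrid,
    areas: RasterGrid,
) -> RangeSummary:
    """All per-species scalar range statistics in one pass."""
    a_cur = range_area(binary_current, areas)
    a_fut = range_area(binary_future, areas)
    c = csh(a_cur, a_fut)
    e_cur = mean_elevation(binary_current, dem, areas)
    e_fut = mean_elevation(binary_future, dem, areas)
    if e_cur is not None and e_fut is not None:
        shift = e_fut - e_cur
        shift_pct = (shift / e_cur * 100.0) if e_cur != 0 else None
    else:
        shift = shift_pct = None
    return RangeSummary(
        species_id=species_id,
        area_current_km2=a_cur,
        area_future_km2=a_fut,
        csh_pct=c,
        csh_class=csh_class(c),
        drastic=(c is not None and c <= DRASTIC_CSH_PCT),
        mean_elev_current_m=e_cur,
        mean_elev_future_m=e_fut,
        elev_shift_m=shift,
        elev_shift_pct=shift_pct,
    )


def deviational_ellipse(lons, lats, weights=None) -> Ellipse:
    """1-SD covariance ellipse of points on a local equirectangular plane.

    Coordinates are projected about their centroid (x east, y north, km);
    the ellipse axes are the covariance eigenvectors and the azimuth is the
    major-axis direction clockwise from north in [0, 180).
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lons.size < 3:
        raise ValueError("deviational ellipse needs >= 3 points")
    w = np.ones_like(lons) if weights is None else np.asarray(weights, dtype=float)
    lon0 = np.average(lons, weights=w)
    lat0 = np.average(lats, weights=w)
    kx = EARTH_RADIUS_KM * math.radians(1.0) * math.cos(math.radians(lat0))
    ky = EARTH_RADIUS_KM * math.radians(1.0)
    x = (lons - lon0) * kx
    y = (lats - lat0) * ky
    cov = np.cov(np.vstack([x, y]), aweights=w)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12 * max(evals[1], 1e-300):
        raise ValueError("degenerate (collinear) point set")
    major = evecs[:, 1]
    azimuth = math.degrees(math.atan2(major[0], major[1])) % 180.0
    return Ellipse(
        center_lon=float(lon0),
        center_lat=float(lat0),
        semi_major_km=float(math.sqrt(evals[1])),
        semi_minor_km=float(math.sqrt(evals[0])),
        azimuth_deg=float(azimuth),
    )


def ellipse_geojson(e: Ellipse, n_vertices: int = 64) -> dict:
    """Ellipse boundary as a GeoJSON Polygon feature (lon/lat vertices)."""
    kx = EARTH_RADIUS_KM * math.radians(1.0) * math.cos(math.radians(e.center_lat))
    ky = EARTH_RADIUS_KM * math.radians(1.0)
    az = math.radians(e.azimuth_deg)
    t = np.linspace(0, 2 * np.pi, n_vertices + 1)
    # major axis points along (sin az, cos az) in (east, north)
    ex = e.semi_major_km * np.cos(t) * math.sin(az) + e.semi_minor_km * np.sin(t) * math.cos(az)
    ny = e.semi_major_km * np.cos(t) * math.cos(az) - e.semi_minor_km * np.sin(t) * math.sin(az)
    coords = [[float(e.center_lon + x / kx), float(e.center_lat + y / ky)] for x, y in zip(ex, ny)]
    return {
        "type": "Feature",
        "properties": {
            "semi_major_km": e.semi_major_km,
            "semi_minor_km": e.semi_minor_km,
            "azimuth_deg": e.azimuth_deg,
        },
        "geometry": {"type": "Polygon", "coordinates": [coords]},
    }
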