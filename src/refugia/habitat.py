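"""Habitat degradation and quality (InVEST-style model).

Each threat ``r`` has an intensity raster ``r_y`` (its source cells), a
maximum effective distance ``d_rmax`` (km), a weight ``w_r`` and a
distance-decay kind. The degradation score of a cell ``x`` carrying LULC
class ``j`` is

    D_xj = sum_r (w_r / sum_r w_r) * sum_{y in Y_r} r_y * i_rxy * beta_x * S_jr

with ``i_rxy`` a decay from 1 at the source to 0 at ``d_rmax`` — linear
``1 - d/d_rmax`` or exponential ``exp(-2.99 d/d_rmax)`` — and ``S_jr`` the
sensitivity of class ``j`` to threat ``r``. Quality discounts the per-class
habitat suitability ``H_j`` through a half-saturation response:

    Q_xj = H_j * (1 - D^z / (D^z + k^z))

so ``Q = H_j`` when undegraded and ``Q = H_j/2`` at ``D = k``.

Distances are great-circle distances between cell centers; source sets
``Y_r`` are all cells with positive intensity, unnormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import RasterGrid, combined_valid_mask, great_circle_km, require_all_aligned

__all__ = [
    "ThreatSpec",
    "SensitivityMatrix",
    "HQParams",
    "decay_weight",
    "degradation",
    "quality",
]

# InVEST uses exp(-2.99 d/dmax) so the exponential kernel carries ~5% of its
# strength at the maximum effective distance.
EXP_DECAY_RATE = 2.99


@dataclass
class ThreatSpec:
    """One threat layer and its degradation parameters."""

    name: str
    intensity: RasterGrid
    d_rmax_km: float
    weight: float
    decay: str = "linear"  # "linear" | "exponential"

    def __post_init__(self):
        if self.d_rmax_km <= 0:
            raise ValueError(f"threat {self.name}: d_rmax must be > 0")
        if self.weight <= 0:
            raise ValueError(f"threat {self.name}: weight must be > 0")
        if self.decay not in ("linear", "exponential"):
            raise ValueError(f"threat {self.name}: unknown decay kind {self.decay!r}")
        if not np.all(np.isfinite(self.intensity.values[self.intensity.mask])):
            raise ValueError(f"threat {self.name}: intensity must be finite")


@dataclass
class SensitivityMatrix:
    """Per-LULC-class habitat suitability H_j and sensitivity S_jr.

    ``habitat``: class id -> H_j in [0, 1].
    ``sensitivity``: class id -> {threat name -> S_jr in [0, 1]}.
    """

    habitat: dict[int, float]
    sensitivity: dict[int, dict[str, float]]

    def __post_init__(self):
        for j, h in self.habitat.items():
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"H for LULC {j} outside [0,1]: {h}")
        for j, row in self.sensitivity.items():
            for r, s in row.items():
                if not 0.0 <= s <= 1.0:
                    raise ValueError(f"S for LULC {j}, threat {r} outside [0,1]: {s}")

    def s_layer(self, lulc: RasterGrid, threat_name: str) -> np.ndarray:
        """S_jr per cell for one threat, resolved through the LULC map."""
        classes = np.unique(lulc.values[lulc.mask]).astype(int)
        out = np.zeros(lulc.shape, dtype=float)
        for j in classes:
            if j not in self.sensitivity:
                raise KeyError(f"LULC class {j} missing from sensitivity matrix")
            out[lulc.values == j] = self.sensitivity[j].get(threat_name, 0.0)
        return out

    def h_layer(self, lulc: RasterGrid) -> np.ndarray:
        classes = np.unique(lulc.values[lulc.mask]).astype(int)
        out = np.zeros(lulc.shape, dtype=float)
        for j in classes:
            if j not in self.habitat:
                raise KeyError(f"LULC class {j} missing from sensitivity matrix")
            out[lulc.values == j] = self.habitat[j]
        return out


@dataclass
class HQParams:
    """Half-saturation constant k, exponent z, optional accessibility raster."""

    k: float = 0.5
    z: float = 2.5
    accessibility: RasterGrid | None = None

    def __post_init__(self):
        if self.k <= 0 or self.z <= 0:
            raise ValueError("k and z must be > 0")


def decay_weight(d_xy_km, d_rmax_km: float, decay: str):
    """Distance-decay impact weight in [0, 1]; 0 beyond d_rmax.

    Accepts scalar or array distances (km).
    """
    d = np.asarray(d_xy_km, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative distance")
    if decay == "linear":
        w = 1.0 - d / d_rmax_km
    elif decay == "exponential":
        w = np.exp(-EXP_DECAY_RATE * d / d_rmax_km)
    else:
        raise ValueError(f"unknown decay kind {decay!r}")
    w = np.where(d > d_rmax_km, 0.0, w)
    w = np.clip(w, 0.0, 1.0)
    return float(w) if np.isscalar(d_xy_km) else w


def _threat_exposure(threat: ThreatSpec, template: RasterGrid) -> np.ndarray:
    """sum_y r_y * i_rxy for every cell x, by looping over source cells and
    accumulating into the window of cells within d_rmax."""
    template.require_aligned(threat.intensity, f"threat {threat.name}")
    n_rows, n_cols = template.shape
    t = template.transform
    lats = template.center_lats()
    lons = template.center_lons()

    intens = np.where(threat.intensity.mask, threat.intensity.values, 0.0)
    src_rows, src_cols = np.nonzero(intens > 0)
    exposure = np.zeros((n_rows, n_cols), dtype=float)
    if len(src_rows) == 0:
        return exposure

    # window half-width: d_rmax along a meridian plus one guard cell; widen
    # east-west by the worst-case cos(lat) of the grid
    km_per_deg = 2 * np.pi * 6371.0 / 360.0
    half_lat = int(np.ceil(threat.d_rmax_km / (km_per_deg * t.cell_size))) + 1
    min_cos = max(np.min(np.cos(np.radians(lats))), 1e-6)
    half_lon = int(np.ceil(threat.d_rmax_km / (km_per_deg * t.cell_size * min_cos))) + 1

    for r0, c0, ry in zip(src_rows, src_cols, intens[src_rows, src_cols]):
        ra, rb = max(0, r0 - half_lat), min(n_rows, r0 + half_lat + 1)
        ca, cb = max(0, c0 - half_lon), min(n_cols, c0 + half_lon + 1)
        wlon, wlat = np.meshgrid(lons[ca:cb], lats[ra:rb])
        d = great_circle_km(lons[c0], lats[r0], wlon, wlat)
        exposure[ra:rb, ca:cb] += ry * decay_weight(d, threat.d_rmax_km, threat.decay)
    return exposure


def degradation(
    lulc: RasterGrid,
    threats: list[ThreatSpec],
    sensitivity: SensitivityMatrix,
    params: HQParams | None = None,
) -> RasterGrid:
    """Habitat degradation score D per cell (weight-normalized over threats)."""
    params = params or HQParams()
    for th in threats:
        lulc.require_aligned(th.intensity, f"threat {th.name}")
    if params.accessibility is not None:
        lulc.require_aligned(params.accessibility, "accessibility")
        beta = np.where(params.accessibility.mask, params.accessibility.values, 0.0)
    else:
        beta = np.ones(lulc.shape)

    w_total = sum(th.weight for th in threats)
    d_vals = np.zeros(lulc.shape, dtype=float)
    mask = lulc.mask.copy()
    for th in threats:
        mask &= th.intensity.mask
        s_jr = sensitivity.s_layer(lulc, th.name)
        d_vals += (th.weight / w_total) * _threat_exposure(th, lulc) * beta * s_jr
    return lulc.copy_with(d_vals, mask)


def quality(
    d_grid: RasterGrid,
    lulc: RasterGrid,
    sensitivity: SensitivityMatrix,
    params: HQParams | None = None,
) -> RasterGrid:
    """Habitat quality Q = H_j * (1 - D^z / (D^z + k^z)) per cell."""
    params = params or HQParams()
    d_grid.require_aligned(lulc, "quality")
    h = sensitivity.h_layer(lulc)
    d = np.where(d_grid.mask, d_grid.values, 0.0)
    dz = np.power(d, params.z)
    q = h * (1.0 - dz / (dz + params.k**params.z))
    return lulc.copy_with(q, d_grid.mask & lulc.mask)
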