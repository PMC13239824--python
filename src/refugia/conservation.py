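"""Hotspots, species-loss surfaces, priority areas and protection gaps.

Hotspots are cells in the top q-fraction (default 5%) of a surface:
threshold = (1-q) quantile of valid-cell values, with every tie at the
threshold included. The combined biodiversity hotspot is the union of the
per-layer (SR, PD, HQ) masks. Priority conservation areas intersect
high-diversity/quality cells with cells of high projected species loss
(top 10% by default); a strict all-four-intersection rule is selectable.

Protection coverage is the percent of a species' current range area inside
protected areas; species covered 0-20% (inclusive) are gap species, and
those under 5% are severely underprotected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .grid import RasterGrid, combined_valid_mask, require_all_aligned

__all__ = [
    "top_fraction_mask",
    "hotspots",
    "HotspotSet",
    "species_loss",
    "priority_areas",
    "protection_coverage",
    "CoverageReport",
    "rasterize_polygons",
    "read_polygons_geojson",
    "write_polygons_geojson",
]

GAP_COVERAGE_PCT = 20.0
SEVERE_COVERAGE_PCT = 5.0


def top_fraction_mask(layer: RasterGrid, q: float) -> RasterGrid:
    """Mask of the top q-fraction of valid cells, ties at the cut included."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    vals = layer.values[layer.mask].astype(float)
    if vals.size == 0:
        raise ValueError("all-nodata layer")
    thr = float(np.quantile(vals, 1.0 - q))
    if np.all(vals == vals[0]):
        warnings.warn("constant layer: the whole valid area is in the top fraction")
    m = layer.mask & (layer.values >= thr)
    return layer.copy_with(m.astype(int), layer.mask)


def _mask_area(mask: RasterGrid, areas: RasterGrid) -> float:
    return float(areas.values[(mask.values > 0) & mask.mask].sum())


@dataclass
class HotspotSet:
    masks: dict[str, RasterGrid]  # per-layer top-q masks (SR, PD, HQ)
    union: RasterGrid
    q: float
    overlap_fractions: dict[str, float]  # area fractions of the union (Venn)
    union_fraction_of_valid: float
    stratum_probability: pd.DataFrame  # P(mask | mountain), P(mask | non-mountain)


def hotspots(
    sr: RasterGrid,
    pd_layer: RasterGrid,
    hq: RasterGrid,
    areas: RasterGrid,
    q: float = 0.05,
    mountain_mask: RasterGrid | None = None,
) -> HotspotSet:
    """Per-layer top-q masks, their union, Venn overlap fractions (on cell
    areas) and mountain vs non-mountain occurrence probabilities."""
    layers = {"SR": sr, "PD": pd_layer, "HQ": hq}
    require_all_aligned(list(layers.values()) + [areas], "hotspots")
    masks = {k: top_fraction_mask(v, q) for k, v in layers.items()}
    valid = combined_valid_mask(list(layers.values()))
    union_m = np.zeros(sr.shape, dtype=bool)
    for m in masks.values():
        union_m |= m.values > 0
    union_m &= valid
    union = sr.copy_with(union_m.astype(int), valid)

    a = areas.values
    union_area = float(a[union_m].sum())
    in_m = {k: (m.values > 0) & valid for k, m in masks.items()}
    combos = {
        "SR_only": in_m["SR"] & ~in_m["PD"] & ~in_m["HQ"],
        "PD_only": in_m["PD"] & ~in_m["SR"] & ~in_m["HQ"],
        "HQ_only": in_m["HQ"] & ~in_m["SR"] & ~in_m["PD"],
        "SR_PD": in_m["SR"] & in_m["PD"] & ~in_m["HQ"],
        "SR_HQ": in_m["SR"] & in_m["HQ"] & ~in_m["PD"],
        "PD_HQ": in_m["PD"] & in_m["HQ"] & ~in_m["SR"],
        "SR_PD_HQ": in_m["SR"] & in_m["PD"] & in_m["HQ"],
    }
    overlaps = {
        k: (float(a[sel].sum()) / union_area if union_area > 0 else 0.0)
        for k, sel in combos.items()
    }
    valid_area = float(a[valid].sum())
    union_frac = union_area / valid_area if valid_area > 0 else 0.0

    prob = pd.DataFrame(index=["mountain", "non_mountain"], dtype=float)
    if mountain_mask is not None:
        sr.require_aligned(mountain_mask, "hotspots mountain mask")
        mnt = (mountain_mask.values > 0) & valid
        for k, sel in {**in_m, "union": union_m}.items():
            col = []
            for stratum in (mnt, valid & ~mnt):
                s_area = float(a[stratum].sum())
                col.append(float(a[sel & stratum].sum()) / s_area if s_area > 0 else np.nan)
            prob[k] = col
    return HotspotSet(masks, union, q, overlaps, union_frac, prob)


def species_loss(current: list[RasterGrid], future: list[RasterGrid]) -> RasterGrid:
    """Per-cell count of species present now and absent in the future."""
    if len(current) != len(future):
        raise ValueError("current/future stacks differ in length")
    require_all_aligned(current + future, "species_loss")
    mask = combined_valid_mask(current + future)
    loss = np.zeros(current[0].shape, dtype=int)
    for b_cur, b_fut in zip(current, future):
        loss += ((b_cur.values > 0) & ~(b_fut.values > 0)).astype(int)
    loss[~mask] = 0
    return current[0].copy_with(loss, mask)


def priority_areas(
    sr: RasterGrid,
    pd_layer: RasterGrid,
    hq: RasterGrid,
    loss: RasterGrid,
    q: float = 0.10,
    rule: str = "union_diversity_and_loss",
) -> RasterGrid:
    """Priority conservation mask.

    Default rule: (top-q SR | top-q PD | top-q HQ) & top-q loss. The
    ``strict`` rule intersects all four top-q masks; it is always a subset
    of the default.
    """
    require_all_aligned([sr, pd_layer, hq, loss], "priority_areas")
    m_sr = top_fraction_mask(sr, q).values > 0
    m_pd = top_fraction_mask(pd_layer, q).values > 0
    m_hq = top_fraction_mask(hq, q).values > 0
    m_loss = top_fraction_mask(loss, q).values > 0
    if rule == "union_diversity_and_loss":
        m = (m_sr | m_pd | m_hq) & m_loss
    elif rule == "strict":
        m = m_sr & m_pd & m_hq & m_loss
    else:
        raise ValueError(f"unknown priority rule {rule!r}")
    valid = combined_valid_mask([sr, pd_layer, hq, loss])
    return sr.copy_with((m & valid).astype(int), valid)


@dataclass
class CoverageReport:
    per_species: pd.DataFrame  # species, coverage_pct, gap, severe
    pa_fraction_of_area: float
    priority_overlap_pct: float | None


def protection_coverage(
    species_binaries: dict[str, RasterGrid],
    pa_mask: RasterGrid,
    areas: RasterGrid,
    priority: RasterGrid | None = None,
) -> CoverageReport:
    """Percent of each species' range inside protected areas, gap flags, and
    the priority-area / protected-area overlap percent."""
    grids = list(species_binaries.values()) + [pa_mask, areas]
    require_all_aligned(grids, "protection_coverage")
    pa = (pa_mask.values > 0) & pa_mask.mask
    a = areas.values
    rows = []
    for sp, b in species_binaries.items():
        pres = (b.values > 0) & b.mask
        range_area = float(a[pres].sum())
        if range_area <= 0:
            rows.append({"species": sp, "coverage_pct": np.nan, "gap": False, "severe": False})
            continue
        cov = 100.0 * float(a[pres & pa].sum()) / range_area
        rows.append(
            {
                "species": sp,
                "coverage_pct": cov,
                # inclusive boundary, robust to float rounding of the ratio
                "gap": cov <= GAP_COVERAGE_PCT + 1e-9,
                "severe": cov < SEVERE_COVERAGE_PCT,
            }
        )
    per_species = pd.DataFrame(rows)

    valid_area = float(a[pa_mask.mask].sum())
    pa_frac = float(a[pa].sum()) / valid_area if valid_area > 0 else np.nan
    overlap = None
    if priority is not None:
        pa_mask.require_aligned(priority, "protection_coverage priority")
        pri = (priority.values > 0) & priority.mask
        pri_area = float(a[pri].sum())
        overlap = 100.0 * float(a[pri & pa].sum()) / pri_area if pri_area > 0 else np.nan
    return CoverageReport(per_species, pa_frac, overlap)


# ---------------------------------------------------------------------------
# Protected-area polygons (GeoJSON) <-> raster mask
# ---------------------------------------------------------------------------

def read_polygons_geojson(path) -> list[shapely.Geometry]:
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    return [shape(f["geometry"]) for f in feats]


def write_polygons_geojson(geoms, path, properties=None) -> None:
    props = properties or [{} for _ in geoms]
    gj = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": p, "geometry": mapping(g)}
            for g, p in zip(geoms, props)
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


def rasterize_polygons(geoms, template: RasterGrid) -> RasterGrid:
    """0/1 mask on the template grid: a cell is inside iff its center is
    covered by any polygon."""
    lon, lat = template.cell_centers()
    inside = np.zeros(template.shape, dtype=bool)
    merged = shapely.union_all(list(geoms)) if len(list(geoms)) else None
    if merged is not None and not merged.is_empty:
        inside = shapely.intersects_xy(merged, lon.ravel(), lat.ravel()).reshape(template.shape)
    return template.copy_with(inside.astype(int), template.mask.copy())
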