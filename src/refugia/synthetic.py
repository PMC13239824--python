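"""Seeded synthetic dryland-basin generator.

Emulates the statistical structure the analysis assumes for an arid
mountain-fringed river basin: a terrain ramp from southern desert plains
to northern mountains (convex, so plains are vast and near-isothermal
while mountain thermal bands are narrow), temperature falling and
precipitation rising with elevation, rivers descending the terrain by
steepest descent, human land use (cropland/urban/roads) concentrated in
low, near-river cells, threat layers derived from that land use, a
protected-area network biased to the mountains, a simulated phylogeny,
and species occurrences sampled from known Gaussian niche functions.

The future scenario warms the lowlands more than the highlands (an
elevation-dependent temperature increment averaging ``warming_delta``)
and scales precipitation by ``precip_delta_pct``; lowland river-valley
species are therefore *designed* to contract and montane species to
expand, giving parameter-recovery tests a signed expectation. Each
species' true current/future suitability fields and designed
expansion/contraction sign are recorded in the landscape's truth table.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy import ndimage
from shapely.geometry import Point

from .grid import EARTH_RADIUS_KM, EnvStack, RasterGrid, Transform, cell_areas
from .habitat import HQParams, SensitivityMatrix, ThreatSpec

__all__ = [
    "LandscapeConfig",
    "NicheSpec",
    "SyntheticLandscape",
    "generate_landscape",
    "generate_phylogeny",
    "sample_occurrences",
    "default_niches",
    "register_truth",
    "sample_all_occurrences",
    "default_sensitivity",
    "write_landscape",
]

LULC_WATER, LULC_FOREST, LULC_GRASS, LULC_CROP, LULC_URBAN, LULC_BARE = 1, 2, 3, 4, 5, 6

KM_PER_DEG = 2 * np.pi * EARTH_RADIUS_KM / 360.0


@dataclass
class LandscapeConfig:
    """Knobs of the synthetic basin; defaults are the study conditions.

    The grid is 120x120 cells of 0.01 degree (~1 km), spanning an
    Central-Asian-style window (86-87.2 E, 47-48.2 N) with mountains in the north.
    ``warming_delta`` is the *mean* future temperature increment (degC);
    lowlands warm up to 1.5x it and ridge tops 0.5x. ``pa_fraction``
    defaults to 0.1287 (the protected share of the emulated basin).
    """

    n_rows: int = 120
    n_cols: int = 120
    cell_size_deg: float = 0.01
    west: float = 86.0
    north: float = 48.2
    seed: int = 0
    warming_delta: float = 2.0
    precip_delta_pct: float = 5.0
    mountain_elevation_m: float = 1500.0
    pa_fraction: float = 0.1287
    n_species: int = 16
    n_rivers: int = 3

    def __post_init__(self):
        if self.n_rows < 20 or self.n_cols < 20:
            raise ValueError("grid must be at least 20x20")
        if not 0.0 <= self.pa_fraction <= 1.0:
            raise ValueError("pa_fraction must be in [0, 1]")

    @property
    def transform(self) -> Transform:
        return Transform(self.west, self.north, self.cell_size_deg)


@dataclass
class NicheSpec:
    """Ground-truth Gaussian niche of one synthetic species.

    ``responses`` maps environment-layer names to (optimum, breadth);
    suitability is the product of the per-variable Gaussian responses,
    rescaled to [0, 1]. ``east_shift_cells`` > 0 marks a species whose
    future truth field is a designed eastward translation of its current
    field (used to validate centroid-shift recovery) instead of being
    environment-driven.
    """

    species_id: str
    responses: dict[str, tuple[float, float]]
    n_occurrences: int = 20
    guild: str = "lowland"  # lowland | montane
    east_shift_cells: int = 0
    viability_floor: float = 0.45
    # optional dispersal-limited endemism: a Gaussian range-center term
    # (lon, lat, breadth in degrees) multiplied into the suitability product
    spatial_center: tuple[float, float] | None = None
    spatial_breadth_deg: float = 0.14

    def __post_init__(self):
        for var, (_, breadth) in self.responses.items():
            if breadth <= 0:
                raise ValueError(f"{self.species_id}: breadth for {var} must be > 0")
        if self.n_occurrences < 5:
            raise ValueError(f"{self.species_id}: need >= 5 occurrences to survive filtering")

    def raw_product(self, env: EnvStack) -> RasterGrid:
        """Unscaled product of the per-variable Gaussian responses (and the
        optional spatial endemism term)."""
        valid = env.valid_mask()
        s = np.ones(env.template.shape, dtype=float)
        for var, (opt, breadth) in self.responses.items():
            v = env[var].values.astype(float)
            s *= np.exp(-0.5 * ((v - opt) / breadth) ** 2)
        if self.spatial_center is not None:
            lon, lat = env.template.cell_centers()
            d2 = (lon - self.spatial_center[0]) ** 2 + (lat - self.spatial_center[1]) ** 2
            s *= np.exp(-0.5 * d2 / self.spatial_breadth_deg**2)
        s[~valid] = 0.0
        return env.template.copy_with(s, valid)

    def suitability(self, env: EnvStack, scale: float | None = None) -> RasterGrid:
        """Truth suitability rescaled to [0, 1].

        By default the field is rescaled by its own peak; passing ``scale``
        (e.g. the current-scenario peak when computing a future field)
        keeps two scenarios on a common footing, clipped at 1.
        """
        raw = self.raw_product(env)
        peak = raw.values.max() if scale is None else scale
        s = raw.values / peak if peak > 0 else raw.values
        s = np.clip(s, 0.0, 1.0)
        # populations persist only where habitat is adequate: relative
        # suitability below the viability floor is truly unoccupied
        s[s < self.viability_floor] = 0.0
        return raw.copy_with(s)


@dataclass
class SyntheticLandscape:
    config: LandscapeConfig
    env_current: EnvStack
    env_future: EnvStack
    lulc_current: RasterGrid
    lulc_future: RasterGrid
    threats: list[ThreatSpec]
    sensitivity: SensitivityMatrix
    hq_params: HQParams
    pa_polygons: list
    pa_mask: RasterGrid
    mountain_mask: RasterGrid
    truth: dict[str, dict] = field(default_factory=dict)

    @property
    def dem(self) -> RasterGrid:
        return self.env_current["dem"]

    def areas(self) -> RasterGrid:
        return cell_areas(self.env_current.template)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance smoothed Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return f / max(f.std(), 1e-12)


def _trace_river(dem: np.ndarray, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Steepest-descent walk from a start cell to the basin edge.

    When the walk lands in a closed pit it carves through by stepping to
    the lowest unvisited neighbor, so every river reaches the boundary.
    """
    n_rows, n_cols = dem.shape
    path = [start]
    r, c = start
    visited = {start}
    # terminate at the southern edge, or at a side edge once out of the
    # mountains — never at the northern (headwater) edge
    while not (r == n_rows - 1 or ((c == 0 or c == n_cols - 1) and r > int(n_rows * 0.85))):
        best = None
        best_val = np.inf
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols and (rr, cc) not in visited:
                    if dem[rr, cc] < best_val:
                        best_val = dem[rr, cc]
                        best = (rr, cc)
        if best is None:
            return path
        r, c = best
        visited.add(best)
        path.append(best)
    return path


def generate_landscape(config: LandscapeConfig | None = None) -> SyntheticLandscape:
    """Build the full synthetic basin (deterministic under a fixed seed)."""
    cfg = config or LandscapeConfig()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    shape = (cfg.n_rows, cfg.n_cols)
    t = cfg.transform
    template = RasterGrid(np.zeros(shape), t, np.ones(shape, dtype=bool))

    # --- terrain: flat southern plains, a steep mountain front, and a high
    # northern plateau (monotone northward ramp + smoothed relief)
    northness = 1.0 - (np.arange(cfg.n_rows) + 0.5) / cfg.n_rows  # row 0 = north
    s = northness[:, None] * np.ones((1, cfg.n_cols))
    relief = _smooth_field(rng, shape, sigma=4.0)
    ramp = 0.5 * (1.0 + np.tanh((s - 0.62) / 0.14))
    dem = 200.0 + 3000.0 * ramp + relief * (60.0 + 120.0 * s)
    dem = np.maximum(dem, 1.0)

    # slope (m per km) and aspect (deg from north) from DEM gradients
    lat_mid = t.north - cfg.n_rows * t.cell_size / 2.0
    dy_km = t.cell_size * KM_PER_DEG
    dx_km = t.cell_size * KM_PER_DEG * np.cos(np.radians(lat_mid))
    gy, gx = np.gradient(dem, dy_km, dx_km)  # gy: toward south (row direction)
    slope = np.hypot(gx, gy)
    aspect = (np.degrees(np.arctan2(gx, -gy))) % 360.0

    # --- climate: lapse-rate temperature; orographic precipitation with an
    # independent west-east moisture gradient so temperature and
    # precipitation are correlated with elevation (signs forced) without
    # being mutual near-duplicates
    # lapse-rate cooling with elevation plus a meridional (continentality)
    # gradient: the southern desert plains are hotter than the foothill
    # plains at equal elevation
    temp = 22.0 - 6.5 * dem / 1000.0 - 5.0 * s + 0.5 * _smooth_field(rng, shape, 6.0)
    westness = 1.0 - (np.arange(cfg.n_cols) + 0.5) / cfg.n_cols
    precip = (
        100.0
        + 0.2 * dem
        + 250.0 * westness[None, :]
        + 200.0 * _smooth_field(rng, shape, 8.0)
    )
    precip = np.maximum(precip, 10.0)
    temp_seasonality = 34.0 + 0.002 * dem + 2.5 * _smooth_field(rng, shape, 6.0)
    # deliberately collinear warm-quarter temperature (screened out downstream)
    temp_warmq = temp + 8.0 + 0.2 * _smooth_field(rng, shape, 6.0)

    # --- rivers by steepest descent from high-elevation seeds; traced on a
    # smoothed terrain so channels run down-valley instead of wandering
    # through local relief pits
    river = np.zeros(shape, dtype=bool)
    dem_smooth = ndimage.gaussian_filter(dem, 3.0, mode="reflect")
    seed_cols = np.sort(rng.choice(np.arange(5, cfg.n_cols - 5), size=cfg.n_rivers, replace=False))
    # headwaters on the upper mountain front, just below the plateau rim
    for c0 in seed_cols:
        r0 = int(rng.integers(int(cfg.n_rows * 0.18), int(cfg.n_rows * 0.28)))
        for rr, cc in _trace_river(dem_smooth, (r0, int(c0))):
            river[rr, cc] = True
    dist_river = ndimage.distance_transform_edt(~river, sampling=(dy_km, dx_km))

    # one mountain lake (upper river reach) and one lowland lake, so
    # distance-to-lake is not a mere elevation proxy
    lakes = np.zeros(shape, dtype=bool)
    riv_cells = np.argwhere(river)
    if len(riv_cells):
        upper = riv_cells[riv_cells[:, 0] < cfg.n_rows // 4]
        lower = riv_cells[riv_cells[:, 0] > 3 * cfg.n_rows // 4]
        for pool in (upper, lower):
            if len(pool):
                r0, c0 = pool[rng.integers(0, len(pool))]
                lakes[max(0, r0 - 1) : r0 + 2, max(0, c0 - 1) : c0 + 2] = True
    dist_lake = ndimage.distance_transform_edt(~lakes, sampling=(dy_km, dx_km))

    def grid(arr):
        return RasterGrid(np.asarray(arr, dtype=float), t, np.ones(shape, dtype=bool))

    env_current = EnvStack(
        {
            "bio1": grid(temp),
            "bio4": grid(temp_seasonality),
            "bio10": grid(temp_warmq),
            "bio12": grid(precip),
            "dem": grid(dem),
            "slope": grid(slope),
            "aspect": grid(aspect),
            "dist_river": grid(dist_river),
            "dist_lake": grid(dist_lake),
        },
        scenario="current",
    )

    # --- future scenario: elevation-dependent warming, scaled precipitation
    elev_norm = (dem - dem.min()) / max(dem.max() - dem.min(), 1e-9)
    warm_field = cfg.warming_delta * (1.2 - 0.4 * elev_norm)  # lowlands warm most
    precip_future = precip * (1.0 + cfg.precip_delta_pct / 100.0)
    env_future = EnvStack(
        {
            "bio1": grid(temp + warm_field),
            "bio4": grid(temp_seasonality + 0.1 * warm_field),
            "bio10": grid(temp_warmq + warm_field),
            "bio12": grid(precip_future),
            "dem": grid(dem),
            "slope": grid(slope),
            "aspect": grid(aspect),
            "dist_river": grid(dist_river),
            "dist_lake": grid(dist_lake),
        },
        scenario="future",
    )

    # --- LULC: cropland/urban in low, near-river cells
    pressure = np.exp(-dist_river / 5.0) * np.exp(-np.maximum(dem - 300.0, 0.0) / 500.0)
    pressure *= 1.0 + 0.3 * _smooth_field(rng, shape, 3.0)
    lulc = np.full(shape, LULC_GRASS, dtype=float)
    lulc[(dem < 700) & (precip < 300)] = LULC_BARE
    lulc[(dem >= 1200) & (dem < 2600) & (precip > 400)] = LULC_FOREST
    crop_thr = np.quantile(pressure, 0.85)
    urban_thr = np.quantile(pressure, 0.98)
    lulc[pressure >= crop_thr] = LULC_CROP
    lulc[pressure >= urban_thr] = LULC_URBAN
    lulc[river | lakes] = LULC_WATER
    lulc_current = grid(lulc)

    # future: cropland/urban creep into adjacent low cells
    human = (lulc == LULC_CROP) | (lulc == LULC_URBAN)
    fringe = ndimage.binary_dilation(human, iterations=1) & ~human & (dem < 900)
    convert = fringe & (rng.random(shape) < 0.35)
    lulc_fut = lulc.copy()
    lulc_fut[convert] = LULC_CROP
    lulc_future = grid(lulc_fut)

    # --- threats derived from human land use
    road = np.zeros(shape, dtype=bool)
    urb = np.argwhere(lulc == LULC_URBAN)
    if len(urb) >= 2:
        a, b = urb[np.argmin(urb[:, 1])], urb[np.argmax(urb[:, 1])]
        n_pts = 4 * max(abs(b[0] - a[0]), abs(b[1] - a[1])) + 1
        rr = np.linspace(a[0], b[0], n_pts).round().astype(int)
        cc = np.linspace(a[1], b[1], n_pts).round().astype(int)
        road[rr, cc] = True
    threats = [
        ThreatSpec("cropland", grid((lulc == LULC_CROP).astype(float)), 4.0, 0.7, "linear"),
        ThreatSpec("urban", grid((lulc == LULC_URBAN).astype(float)), 8.0, 1.0, "exponential"),
        ThreatSpec("road", grid(road.astype(float)), 2.0, 0.5, "linear"),
    ]

    # --- protected areas: circular reserves biased to the mountains
    pa_polygons = []
    if cfg.pa_fraction > 0:
        n_pa = 3
        deg_area = cfg.n_rows * cfg.n_cols * cfg.cell_size_deg**2
        radius = np.sqrt(cfg.pa_fraction * deg_area / (n_pa * np.pi))
        lat_hi = cfg.north - 0.05 * cfg.n_rows * cfg.cell_size_deg
        lat_lo = cfg.north - 0.35 * cfg.n_rows * cfg.cell_size_deg
        for _ in range(n_pa):
            lon = cfg.west + cfg.cell_size_deg * cfg.n_cols * rng.uniform(0.15, 0.85)
            lat = rng.uniform(lat_lo, lat_hi)
            pa_polygons.append(Point(lon, lat).buffer(radius, quad_segs=32))
    from .conservation import rasterize_polygons

    pa_mask = rasterize_polygons(pa_polygons, template)

    mountain_mask = grid((dem >= cfg.mountain_elevation_m).astype(float))

    return SyntheticLandscape(
        config=cfg,
        env_current=env_current,
        env_future=env_future,
        lulc_current=lulc_current,
        lulc_future=lulc_future,
        threats=threats,
        sensitivity=default_sensitivity(),
        hq_params=HQParams(),
        pa_polygons=pa_polygons,
        pa_mask=pa_mask,
        mountain_mask=mountain_mask,
    )


def default_sensitivity() -> SensitivityMatrix:
    """Habitat suitability and threat sensitivities per LULC class,
    structured like an InVEST sensitivity table for a dryland basin."""
    return SensitivityMatrix(
        habitat={
            LULC_WATER: 0.8,
            LULC_FOREST: 1.0,
            LULC_GRASS: 0.8,
            LULC_CROP: 0.3,
            LULC_URBAN: 0.0,
            LULC_BARE: 0.4,
        },
        sensitivity={
            LULC_WATER: {"cropland": 0.6, "urban": 0.7, "road": 0.4},
            LULC_FOREST: {"cropland": 0.6, "urban": 0.8, "road": 0.5},
            LULC_GRASS: {"cropland": 0.5, "urban": 0.7, "road": 0.4},
            LULC_CROP: {"cropland": 0.0, "urban": 0.3, "road": 0.1},
            LULC_URBAN: {"cropland": 0.0, "urban": 0.0, "road": 0.0},
            LULC_BARE: {"cropland": 0.3, "urban": 0.4, "road": 0.2},
        },
    )


def generate_phylogeny(species_ids: list[str], seed: int = 0) -> dendropy.Tree:
    """Simulated pure-birth tree whose tips are exactly ``species_ids``."""
    if len(species_ids) < 2:
        raise ValueError("need at least 2 species")
    if len(set(species_ids)) != len(species_ids):
        raise ValueError("duplicate species ids")
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=len(species_ids),
        rng=_random.Random(int(seed)),
    )
    leaves = sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label)
    ns = dendropy.TaxonNamespace()
    for leaf, sp in zip(leaves, sorted(species_ids)):
        leaf.taxon = ns.new_taxon(sp)
    tree.taxon_namespace = ns
    tree.is_rooted = True
    return tree


def default_niches(landscape: SyntheticLandscape, seed: int = 0) -> list[NicheSpec]:
    """Default species pool: half montane (high-precip niches, designed to
    expand), half lowland riparian (warm near-river niches, designed to
    contract under amplified lowland warming). Two lowland species are
    additionally marked for an eastward-translation truth scenario."""
    cfg = landscape.config
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    env = landscape.env_current
    valid = env.valid_mask()
    temp = env["bio1"].values[valid]
    precip = env["bio12"].values[valid]
    driv = env["dist_river"].values[valid]
    q1_driv = float(np.quantile(driv, 0.25))
    dem_v = env["dem"].values[valid]
    plateau = dem_v >= np.quantile(dem_v, 0.85)
    t_plateau = float(np.quantile(temp[plateau], 0.90))
    plains = dem_v <= 700.0
    t_plains = temp[plains] if plains.any() else temp

    n = cfg.n_species
    n_mont = n // 2
    specs = []
    for i in range(n):
        sid = f"sp{i:02d}"
        n_occ = int(rng.integers(30, 49))
        if i < n_mont:
            # montane: cold-limited on the upper mountain front — the high
            # plateau just above is observably too cold, so warming opens
            # it up; a broad wet-side moisture affinity keeps them north
            br_t = float(rng.uniform(0.9, 1.2))
            opt_t = t_plateau + 1.18 * br_t + float(rng.uniform(-0.3, 0.1))
            opt_p = float(np.quantile(precip, rng.uniform(0.93, 0.99)))
            br_p = float(rng.uniform(400.0, 600.0))
            specs.append(
                NicheSpec(
                    sid,
                    {"bio1": (opt_t, br_t), "bio12": (opt_p, br_p)},
                    n_occurrences=n_occ,
                    guild="montane",
                )
            )
        else:
            # lowland riparian: narrow warm thermal niche on the foothill
            # fringe of the plains, hugging the rivers; the hotter southern
            # plains are occupied-absent, so models observe both niche edges
            opt_t = float(np.quantile(t_plains, rng.uniform(0.40, 0.60)))
            br_t = float(rng.uniform(0.7, 0.95))
            shift = 12 if i >= n - 2 else 0
            center = None
            if shift:
                # translation-scenario species are dispersal-limited local
                # endemics of the western plains, so the designed eastward
                # shift stays well inside the basin
                t = landscape.config.transform
                center = (
                    t.west + 0.30 * cfg.n_cols * cfg.cell_size_deg,
                    t.north - 0.70 * cfg.n_rows * cfg.cell_size_deg,
                )
                breadth = 12.0 * cfg.cell_size_deg
            specs.append(
                NicheSpec(
                    sid,
                    {"bio1": (opt_t, br_t), "dist_river": (0.0, 0.45 * q1_driv)},
                    n_occurrences=n_occ,
                    guild="lowland",
                    east_shift_cells=shift,
                    spatial_center=center,
                    spatial_breadth_deg=breadth if shift else 0.14,
                )
            )
    return specs


def _truth_fields(landscape: SyntheticLandscape, spec: NicheSpec):
    scale = spec.raw_product(landscape.env_current).values.max()
    cur = spec.suitability(landscape.env_current, scale=scale)
    if spec.east_shift_cells > 0:
        shifted = np.zeros_like(cur.values)
        k = spec.east_shift_cells
        shifted[:, k:] = cur.values[:, :-k]
        fut = cur.copy_with(shifted)
    else:
        # future on the same scale as current, so the designed sign reflects
        # an absolute change in habitat, not a per-scenario renormalization
        fut = spec.suitability(landscape.env_future, scale=scale)
    return cur, fut


def register_truth(landscape: SyntheticLandscape, specs: list[NicheSpec]) -> None:
    """Compute and store each species' truth suitability fields and the
    designed expansion/contraction sign (area change of the >0.5 truth
    range on geodesic cell areas)."""
    areas = landscape.areas().values
    for spec in specs:
        cur, fut = _truth_fields(landscape, spec)
        a_cur = float(areas[(cur.values > 0.5) & cur.mask].sum())
        a_fut = float(areas[(fut.values > 0.5) & fut.mask].sum())
        landscape.truth[spec.species_id] = {
            "niche": spec,
            "suit_current": cur,
            "suit_future": fut,
            "area_current_km2": a_cur,
            "area_future_km2": a_fut,
            "designed_sign": int(np.sign(a_fut - a_cur)),
        }


def sample_occurrences(
    landscape: SyntheticLandscape, spec: NicheSpec, seed: int = 0
) -> pd.DataFrame:
    """Occurrence points for one species: cells drawn without replacement
    with probability proportional to truth suitability, each point placed
    uniformly within its cell."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    suit = spec.suitability(landscape.env_current)
    w = np.where(suit.mask, suit.values, 0.0).ravel()
    pos = np.nonzero(w > 0)[0]
    if spec.n_occurrences > len(pos):
        raise ValueError(
            f"{spec.species_id}: {spec.n_occurrences} occurrences requested but "
            f"only {len(pos)} cells have positive suitability"
        )
    p = w[pos] / w[pos].sum()
    chosen = rng.choice(pos, size=spec.n_occurrences, replace=False, p=p)
    rows, cols = np.unravel_index(chosen, suit.shape)
    t = landscape.config.transform
    lon = t.west + (cols + rng.uniform(0, 1, size=len(cols))) * t.cell_size
    lat = t.north - (rows + rng.uniform(0, 1, size=len(rows))) * t.cell_size
    return pd.DataFrame({"species": spec.species_id, "lon": lon, "lat": lat})


def sample_all_occurrences(
    landscape: SyntheticLandscape, specs: list[NicheSpec], seed: int = 0
) -> pd.DataFrame:
    frames = [
        sample_occurrences(landscape, spec, seed=int(seed) + 1000 + i)
        for i, spec in enumerate(specs)
    ]
    return pd.concat(frames, ignore_index=True)


def write_landscape(landscape: SyntheticLandscape, outdir, specs=None, tree=None, occurrences=None):
    """Persist the fixture set (ASCII grids, CSV, Newick, GeoJSON)."""
    from pathlib import Path

    from .conservation import write_polygons_geojson
    from .grid import write_raster

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for scen, env in (("current", landscape.env_current), ("future", landscape.env_future)):
        for name, g in env.layers.items():
            write_raster(g, outdir / f"env_{scen}_{name}.asc")
    write_raster(landscape.lulc_current, outdir / "lulc_current.asc")
    write_raster(landscape.lulc_future, outdir / "lulc_future.asc")
    for th in landscape.threats:
        write_raster(th.intensity, outdir / f"threat_{th.name}.asc")
    write_raster(landscape.pa_mask, outdir / "pa_mask.asc")
    write_polygons_geojson(landscape.pa_polygons, outdir / "protected_areas.geojson")
    if occurrences is not None:
        occurrences.to_csv(outdir / "occurrences.csv", index=False)
    if tree is not None:
        with open(outdir / "phylogeny.nwk", "w") as fh:
            fh.write(tree.as_string(schema="newick"))
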