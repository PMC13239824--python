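import numpy as np
import pytest
from shapely.geometry import Point, box

from refugia.conservation import (
    hotspots,
    priority_areas,
    protection_coverage,
    rasterize_polygons,
    read_polygons_geojson,
    species_loss,
    top_fraction_mask,
    write_polygons_geojson,
)
from refugia.grid import RasterGrid, Transform, cell_areas


def grid(values, cell=0.1):
    return RasterGrid(np.asarray(values, dtype=float), Transform(86.0, 48.0, cell))


def brute_force_top_mask(values, q):
    """Sort-and-cut with tie inclusion."""
    flat = np.sort(values.ravel())
    thr = np.quantile(flat, 1 - q)
    return values >= thr


class TestTopFraction:
    def test_distinct_values_exact_count(self):
        vals = np.arange(100, dtype=float).reshape(10, 10)
        mask = top_fraction_mask(grid(vals), 0.05)
        assert mask.values.sum() == 5
        assert set(vals[mask.values > 0]) == {95, 96, 97, 98, 99}

    def test_constant_layer_warns_and_masks_all(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = top_fraction_mask(grid(np.ones((5, 5))), 0.05)
        assert mask.values.sum() == 25

    @pytest.mark.parametrize("seed", range(5))
    def test_duplicates_match_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 12, size=(12, 12)).astype(float)  # plenty of ties
        mask = top_fraction_mask(grid(vals), 0.1)
        np.testing.assert_array_equal(mask.values > 0, brute_force_top_mask(vals, 0.1))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            top_fraction_mask(grid(np.ones((3, 3))), 1.5)


class TestHotspots:
    def test_identical_layers_full_triple_overlap(self):
        vals = np.random.default_rng(0).random((20, 20))
        g = grid(vals)
        hs = hotspots(g, g.copy_with(vals), g.copy_with(vals), cell_areas(g), q=0.05)
        assert hs.overlap_fractions["SR_PD_HQ"] == pytest.approx(1.0)
        np.testing.assert_array_equal(hs.union.values, hs.masks["SR"].values)

    def test_disjoint_layers_no_overlap(self):
        a = np.zeros((10, 10)); a[0, :] = np.arange(10) + 1
        b = np.zeros((10, 10)); b[5, :] = np.arange(10) + 1
        c = np.zeros((10, 10)); c[9, :] = np.arange(10) + 1
        g = grid(a)
        hs = hotspots(g, g.copy_with(b), g.copy_with(c), cell_areas(g), q=0.05)
        assert hs.overlap_fractions["SR_PD_HQ"] == 0.0
        assert hs.masks["SR"].values.sum() + hs.masks["PD"].values.sum() + hs.masks[
            "HQ"
        ].values.sum() == hs.union.values.sum()

    def test_union_fraction_bounded(self):
        rng = np.random.default_rng(1)
        g = grid(rng.random((30, 30)))
        hs = hotspots(
            g,
            g.copy_with(rng.random((30, 30))),
            g.copy_with(rng.random((30, 30))),
            cell_areas(g),
            q=0.05,
        )
        assert 0.05 <= hs.union_fraction_of_valid <= 0.15 + 1e-9


class TestSpeciesLoss:
    def test_no_change_no_loss(self):
        b = [grid(np.ones((4, 4))), grid(np.zeros((4, 4)))]
        loss = species_loss(b, [g.copy_with(g.values) for g in b])
        np.testing.assert_array_equal(loss.values, 0)

    def test_total_loss_counts_one(self):
        cur = [grid(np.ones((3, 3)))]
        fut = [grid(np.zeros((3, 3)))]
        np.testing.assert_array_equal(species_loss(cur, fut).values, 1)

    def test_loss_bounded_by_richness(self):
        rng = np.random.default_rng(2)
        cur = [grid((rng.random((8, 8)) > 0.5).astype(float)) for _ in range(6)]
        fut = [grid((rng.random((8, 8)) > 0.5).astype(float)) for _ in range(6)]
        loss = species_loss(cur, fut).values
        sr = sum((g.values > 0).astype(int) for g in cur)
        assert np.all(loss <= sr)

    def test_mismatched_stacks_rejected(self):
        with pytest.raises(ValueError, match="length"):
            species_loss([grid(np.ones((2, 2)))], [])


class TestPriorityAreas:
    def _layers(self, seed=0):
        rng = np.random.default_rng(seed)
        g = grid(rng.random((20, 20)))
        return (
            g,
            g.copy_with(rng.random((20, 20))),
            g.copy_with(rng.random((20, 20))),
            g.copy_with(rng.integers(0, 6, (20, 20)).astype(float)),
        )

    def test_strict_subset_of_default(self):
        for seed in range(5):
            sr, pd_l, hq, loss = self._layers(seed)
            default = priority_areas(sr, pd_l, hq, loss).values > 0
            strict = priority_areas(sr, pd_l, hq, loss, rule="strict").values > 0
            assert np.all(default[strict])

    def test_uniform_loss_tie_gives_diversity_union(self):
        sr, pd_l, hq, _ = self._layers(3)
        loss = sr.copy_with(np.ones((20, 20)))
        with pytest.warns(UserWarning, match="constant"):
            pri = priority_areas(sr, pd_l, hq, loss, q=0.10)
        union = (
            (top_fraction_mask(sr, 0.10).values > 0)
            | (top_fraction_mask(pd_l, 0.10).values > 0)
            | (top_fraction_mask(hq, 0.10).values > 0)
        )
        np.testing.assert_array_equal(pri.values > 0, union)

    def test_disjoint_diversity_and_loss_empty(self):
        a = np.zeros((10, 10)); a[0] = np.arange(10) + 1
        loss_vals = np.zeros((10, 10)); loss_vals[9] = np.arange(10) + 1
        g = grid(a)
        pri = priority_areas(g, g, g, g.copy_with(loss_vals), q=0.05)
        assert pri.values.sum() == 0


class TestCoverage:
    def _world(self):
        t = Transform(86.0, 48.0, 0.1)
        full = RasterGrid(np.ones((10, 10)), t)
        pa = np.zeros((10, 10)); pa[:, :5] = 1  # west half protected
        return full, RasterGrid(pa, t), cell_areas(full)

    def test_full_protection(self):
        full, pa, areas = self._world()
        west = full.copy_with(pa.values.copy())
        rep = protection_coverage({"s": west}, pa, areas)
        row = rep.per_species.iloc[0]
        assert row["coverage_pct"] == pytest.approx(100.0)
        assert not row["gap"]

    def test_no_protection_is_gap_and_severe(self):
        full, pa, areas = self._world()
        east = full.copy_with((pa.values == 0).astype(float))
        rep = protection_coverage({"s": east}, pa, areas)
        row = rep.per_species.iloc[0]
        assert row["coverage_pct"] == pytest.approx(0.0)
        assert row["gap"] and row["severe"]

    def test_half_protection(self):
        full, pa, areas = self._world()
        rep = protection_coverage({"s": full}, pa, areas)
        cov = rep.per_species.iloc[0]["coverage_pct"]
        # west-half cells have the same per-row areas as the east half
        assert cov == pytest.approx(50.0)

    def test_gap_boundary_inclusive_at_20(self):
        t = Transform(86.0, 48.0, 0.1)
        rng_vals = np.zeros((1, 10)); rng_vals[0, :] = 1
        pa_vals = np.zeros((1, 10)); pa_vals[0, :2] = 1  # 20% of an equal-area row
        b = RasterGrid(rng_vals, t)
        rep = protection_coverage({"s": b}, RasterGrid(pa_vals, t), cell_areas(b))
        row = rep.per_species.iloc[0]
        assert row["coverage_pct"] == pytest.approx(20.0)
        assert row["gap"]

    def test_gap_count_monotone_in_pa_growth(self):
        rng = np.random.default_rng(4)
        t = Transform(86.0, 48.0, 0.1)
        species = {
            f"s{i}": RasterGrid((rng.random((15, 15)) > 0.7).astype(float), t) for i in range(8)
        }
        areas = cell_areas(next(iter(species.values())))
        pa_vals = np.zeros((15, 15))
        last = None
        for cols in range(0, 16, 3):
            pa_vals[:, :cols] = 1
            rep = protection_coverage(species, RasterGrid(pa_vals.copy(), t), areas)
            n_gap = int(rep.per_species["gap"].sum())
            if last is not None:
                assert n_gap <= last
            last = n_gap


class TestPolygons:
    def test_geojson_round_trip_and_rasterize(self, tmp_path):
        geoms = [box(86.2, 47.2, 86.6, 47.6), Point(86.8, 47.8).buffer(0.15)]
        path = tmp_path / "pa.geojson"
        write_polygons_geojson(geoms, path, properties=[{"name": "a"}, {"name": "b"}])
        back = read_polygons_geojson(path)
        assert len(back) == 2
        template = RasterGrid(np.zeros((10, 10)), Transform(86.0, 48.0, 0.1))
        mask = rasterize_polygons(back, template)
        # the box spans cell centers in lon [86.25..86.55], lat [47.25..47.55]
        assert mask.values.sum() > 0
        lon, lat = template.cell_centers()
        inside_box = (lon >= 86.2) & (lon <= 86.6) & (lat >= 47.2) & (lat <= 47.6)
        assert np.all(mask.values[inside_box] == 1)
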