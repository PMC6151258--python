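import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist
from scipy.stats import chisquare

from gapstack.envstack import EnvStack
from gapstack.grid import Grid
from gapstack.synthgen import (
    ClimateLayerSpec, VirtualSpecies, default_virtual_species,
    generate_camera_sites, generate_landscape, generate_zones_and_roads,
    sample_occurrences, suitability, true_distribution,
)


class TestGenerateLandscape:
    def test_zero_noise_climate_is_exact_affine_in_elevation(self):
        spec = [ClimateLayerSpec("t", "annual", -0.0065, 10.0, 0.0),
                ClimateLayerSpec("p", "summer", 0.3, 500.0, 0.0)]
        land = generate_landscape(extent=(0, 0, 4000, 4000), cell_size=200,
                                  climate_specs=spec, seed=4)
        np.testing.assert_allclose(land.climate["t"][0],
                                   -0.0065 * land.elevation + 10.0, rtol=0, atol=1e-9)
        np.testing.assert_allclose(land.climate["p"][0],
                                   0.3 * land.elevation + 500.0, rtol=0, atol=1e-9)

    def test_flat_terrain_has_zero_slope(self):
        land = generate_landscape(extent=(0, 0, 2000, 2000), cell_size=100,
                                  elev_range=(1000.0, 1000.0), seed=1)
        assert np.all(land.elevation == 1000.0)
        assert np.all(land.slope == 0.0)

    def test_default_elevation_spans_reserve_relief(self):
        land = generate_landscape(seed=0)
        assert land.elevation.min() == pytest.approx(375.0, abs=1e-9)
        assert land.elevation.max() == pytest.approx(2118.0, abs=1e-9)
        assert np.all(land.slope >= 0)

    def test_nine_variable_default_stack(self):
        env = generate_landscape(seed=0).env_stack()
        assert len(env.layers) == 9
        assert env.topography == {"elevation", "slope"}
        seasons = [env.season[n] for n in env.names if n not in env.topography]
        assert sorted(seasons) == ["annual", "annual", "annual",
                                   "summer", "summer", "winter", "winter"]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            generate_landscape(extent=(0, 0, 600, 600), cell_size=200)
        with pytest.raises(ValueError):
            generate_landscape(cell_size=-10)
        with pytest.raises(ValueError):
            generate_landscape(n_climate_layers=1)

    def test_deterministic_per_seed(self):
        a = generate_landscape(seed=9)
        b = generate_landscape(seed=9)
        np.testing.assert_array_equal(a.elevation, b.elevation)
        for name in a.climate:
            np.testing.assert_array_equal(a.climate[name][0], b.climate[name][0])


def _line_stack(values):
    """1-row stack with a single layer 'v' holding the given values."""
    vals = np.asarray(values, dtype=float)[None, :]
    g = Grid(xmin=0, ymin=0, cell_size=10, nrows=1, ncols=vals.shape[1])
    return EnvStack(layers={"v": vals}, season={"v": "annual"}, grid=g)


class TestSuitability:
    def test_niche_center_scores_one(self):
        stack = _line_stack([3.0, 5.0, 8.0])
        vs = VirtualSpecies("s", "mammal", {"v": (5.0, 2.0)})
        s = suitability(vs, stack)
        assert s[0, 1] == pytest.approx(1.0)
        assert np.all((s >= 0) & (s <= 1))

    def test_one_breadth_from_optimum_gives_exp_half(self):
        stack = _line_stack([7.0])
        vs = VirtualSpecies("s", "mammal", {"v": (5.0, 2.0)})
        assert suitability(vs, stack)[0, 0] == pytest.approx(np.exp(-0.5))

    def test_infinite_breadth_is_uniformly_suitable(self):
        stack = _line_stack([-100.0, 0.0, 1e6])
        vs = VirtualSpecies("s", "mammal", {"v": (5.0, np.inf)})
        np.testing.assert_allclose(suitability(vs, stack), 1.0)

    def test_missing_niche_variable_raises(self):
        stack = _line_stack([1.0])
        vs = VirtualSpecies("s", "mammal", {"w": (0.0, 1.0)})
        with pytest.raises(KeyError, match="w"):
            suitability(vs, stack)

    def test_nonpositive_breadth_rejected(self):
        with pytest.raises(ValueError, match="breadth"):
            VirtualSpecies("s", "mammal", {"v": (0.0, 0.0)})


class TestTrueDistribution:
    def test_half_threshold_inverts_to_gaussian_half_width(self):
        xs = np.linspace(-10, 10, 201)
        stack = _line_stack(xs)
        vs = VirtualSpecies("s", "mammal", {"v": (1.5, 2.0)}, prevalence_threshold=0.5)
        present = true_distribution(vs, stack)[0]
        half_width = 2.0 * np.sqrt(2.0 * np.log(2.0))
        expected = np.abs(xs - 1.5) <= half_width + 1e-12
        np.testing.assert_array_equal(present, expected)

    def test_threshold_limits(self):
        stack = _line_stack(np.linspace(-3, 3, 50))
        vs = VirtualSpecies("s", "mammal", {"v": (0.0, 1.0)}, prevalence_threshold=1e-12)
        assert true_distribution(vs, stack).all()
        tight = VirtualSpecies("s", "mammal", {"v": (0.0, 1.0)},
                               prevalence_threshold=1.0 - 1e-12)
        present = true_distribution(tight, stack)[0]
        assert present.sum() <= 2  # only cells essentially at the optimum

    def test_threshold_outside_unit_interval_rejected(self):
        stack = _line_stack([0.0])
        vs = VirtualSpecies("s", "mammal", {"v": (0.0, 1.0)}, prevalence_threshold=1.0)
        with pytest.raises(ValueError):
            true_distribution(vs, stack)


class TestZones:
    def test_zero_fractions_leave_everything_outside(self, landscape):
        land, _, _ = landscape
        zones, _ = generate_zones_and_roads(land, zone_fractions=(0, 0, 0), seed=0)
        assert zones.zone_areas()["outside"] == pytest.approx(land.grid.area_km2)

    def test_reserve_zone_areas_on_142km2_landscape(self):
        # a 60x60 landscape totalling exactly 142.47 km2, zoned with the
        # emulated reserve's core/buffer/experimental areas
        cs = np.sqrt(142.47e6 / 3600.0)
        land = generate_landscape(extent=(0, 0, 60 * cs, 60 * cs), cell_size=cs, seed=2)
        total = land.grid.area_km2
        assert total == pytest.approx(142.47)
        fr = (37.95 / 142.47, 24.04 / 142.47, 80.48 / 142.47)
        zones, _ = generate_zones_and_roads(land, zone_fractions=fr, seed=2)
        areas = zones.zone_areas()
        cell = land.grid.cell_area_km2
        assert areas["core"] == pytest.approx(37.95, abs=cell)
        assert areas["buffer_zone"] == pytest.approx(24.04, abs=cell)
        assert areas["experimental"] == pytest.approx(80.48, abs=cell)

    def test_invalid_fractions_rejected(self, landscape):
        land, _, _ = landscape
        with pytest.raises(ValueError):
            generate_zones_and_roads(land, zone_fractions=(-0.1, 0.2, 0.2))
        with pytest.raises(ValueError):
            generate_zones_and_roads(land, zone_fractions=(0.5, 0.4, 0.3))

    @settings(max_examples=20, deadline=None)
    @given(st.tuples(st.floats(0, 0.5), st.floats(0, 0.3), st.floats(0, 0.2)))
    def test_partition_property(self, fractions):
        land = generate_landscape(extent=(0, 0, 3000, 3000), cell_size=150, seed=5)
        zones, _ = generate_zones_and_roads(land, zone_fractions=fractions, seed=5)
        areas = zones.zone_areas()
        # the four labels tile the landscape exactly
        assert sum(areas[z] for z in ("core", "buffer_zone", "experimental", "outside")) \
            == pytest.approx(land.grid.area_km2)
        cell = land.grid.cell_area_km2
        total = land.grid.n_cells
        for frac, label in zip(fractions, ("core", "buffer_zone", "experimental")):
            assert areas[label] == pytest.approx(frac * total * cell, abs=1.5 * cell)

    def test_roads_cross_outer_region(self, landscape):
        land, zones, roads = landscape
        assert len(roads) == 2
        for road in roads:
            r, c = land.grid.points_to_cells(np.array(road.coords)[:, :2])
            labels = zones.zone[r, c]
            assert np.isin(labels, [0, 3]).any()  # outside or experimental


class TestCameraSites:
    def test_pairwise_spacing_exceeds_400m(self, landscape):
        land, zones, _ = landscape
        sites = generate_camera_sites(land, seed=3)
        assert pdist(sites[["x", "y"]].to_numpy()).min() > 400.0
        in_zone = generate_camera_sites(land, zone_mask=zones, seed=3)
        assert 0 < len(in_zone) < len(sites)


class TestSampleOccurrences:
    def test_zero_requested_gives_empty_frame(self, landscape):
        land, _, _ = landscape
        vs = default_virtual_species(land, seed=1)[0]
        df = sample_occurrences(vs, land, 0, seed=0)
        assert len(df) == 0

    def test_every_record_lies_in_a_true_presence_cell(self, landscape):
        land, _, _ = landscape
        vs = default_virtual_species(land, seed=1)[0]
        truth = true_distribution(vs, land)
        df = sample_occurrences(vs, land, 200, bias_strength=0.002, seed=7)
        r, c = land.grid.points_to_cells(df[["x", "y"]].to_numpy())
        assert truth[r, c].all()
        # camera records snap to the site design and carry timestamps
        cam = df[df["source"] == "camera"]
        assert cam["site_id"].notna().all() and cam["timestamp"].notna().all()

    def test_road_bias_pulls_samples_toward_roads(self, landscape):
        from gapstack.synthgen import distance_to_roads
        land, _, roads = landscape
        vs = default_virtual_species(land, seed=1)[1]
        d = distance_to_roads(roads, land.grid)

        def mean_dist(bias):
            df = sample_occurrences(vs, land, 400, bias_strength=bias, seed=21)
            r, c = land.grid.points_to_cells(df[["x", "y"]].to_numpy())
            return d[r, c].mean()

        assert mean_dist(0.003) < mean_dist(0.0)

    def test_unbiased_sampling_is_uniform_over_presence_cells(self):
        land = generate_landscape(extent=(0, 0, 3000, 3000), cell_size=300, seed=13)
        vs = VirtualSpecies("u", "mammal", {"elevation": (1200.0, 600.0)},
                            prevalence_threshold=0.5)
        truth = true_distribution(vs, land)
        n_cells = int(truth.sum())
        assert n_cells >= 5
        df = sample_occurrences(vs, land, 300 * n_cells,
                                sources_mix={"transect": 1.0}, bias_strength=0.0,
                                seed=3)
        r, c = land.grid.points_to_cells(df[["x", "y"]].to_numpy())
        flat = r * land.grid.ncols + c
        counts = pd.Series(flat).value_counts().reindex(
            np.flatnonzero(truth.ravel()), fill_value=0)
        assert chisquare(counts.to_numpy()).pvalue > 1e-3

    def test_seasonal_timestamps(self, landscape):
        land, _, _ = landscape
        summer = [s for s in default_virtual_species(land, seed=1)
                  if s.group == "summer_bird"][0]
        df = sample_occurrences(summer, land, 100, seed=5)
        ts = df.loc[df["timestamp"].notna(), "timestamp"]
        assert ts.dt.month.isin([5, 6, 7, 8, 9]).all()

    def test_species_without_presence_raises(self, landscape):
        land, _, _ = landscape
        vs = VirtualSpecies("ghost", "mammal", {"elevation": (10000.0, 10.0)},
                            prevalence_threshold=0.9)
        with pytest.raises(ValueError, match="ghost"):
            sample_occurrences(vs, land, 5, seed=0)

    def test_deterministic_per_seed(self, landscape):
        land, _, _ = landscape
        vs = default_virtual_species(land, seed=1)[0]
        a = sample_occurrences(vs, land, 50, seed=17)
        b = sample_occurrences(vs, land, 50, seed=17)
        pd.testing.assert_frame_equal(a, b)

    def test_bad_sources_mix_rejected(self, landscape):
        land, _, _ = landscape
        vs = default_virtual_species(land, seed=1)[0]
        with pytest.raises(ValueError, match="sum"):
            sample_occurrences(vs, land, 10, sources_mix={"camera": 0.5}, seed=0)
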