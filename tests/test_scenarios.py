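"""Scenario overlays, neighborhood/water-quality rules and intersections."""

import dataclasses

import numpy as np
import pytest

from reforest.cascade import area_summary, run_cascade
from reforest.raster_core import Grid, RasterError, pixel_area
from reforest.scenarios import (
    ScenarioSpec,
    apply_scenario,
    combination_areas,
    default_scenarios,
    forest_neighborhood_mask,
    run_scenarios,
    water_quality_mask,
)
from reforest.synthetic import (
    LANDFORM_FLOODPLAIN,
    LANDFORM_UPLAND,
    SLOPE_FLAT,
    SLOPE_MODERATE,
    SLOPE_STEEP,
    SyntheticConfig,
    generate_bundle,
)
from tests.conftest import make_grid


class TestForestNeighborhood:
    def cover(self, values, px=0.125, north=1.0):
        return make_grid(np.asarray(values, dtype=float), px=px, north=north)

    def test_full_cover_all_ones(self):
        mask = forest_neighborhood_mask(self.cover(np.ones((8, 8))), 40.0, 0.30)
        assert mask.values.min() == 1

    def test_no_cover_all_zeros(self):
        mask = forest_neighborhood_mask(self.cover(np.zeros((8, 8))), 40.0, 0.30)
        assert mask.values.max() == 0

    def test_single_forest_cell_matches_window_enumeration(self):
        vals = np.zeros((9, 9))
        vals[4, 4] = 1.0
        cover = self.cover(vals)
        radius = 30.0
        mask = forest_neighborhood_mask(cover, radius, 0.30)
        # explicit brute-force window scan with the same membership rule
        from reforest.scenarios import KM_PER_DEG

        geom = cover.geometry
        lat_c = np.radians(geom.lat_centers())
        lon_c = np.radians(geom.lon_centers())
        R = 6371.0072
        expected = np.zeros((9, 9), dtype=np.uint8)
        for i in range(9):
            for j in range(9):
                members = []
                for k in range(9):
                    for l in range(9):
                        a = (
                            np.sin((lat_c[k] - lat_c[i]) / 2) ** 2
                            + np.cos(lat_c[i]) * np.cos(lat_c[k])
                            * np.sin((lon_c[l] - lon_c[j]) / 2) ** 2
                        )
                        d = 2 * R * np.arcsin(np.sqrt(a))
                        if d <= radius:
                            members.append(vals[k, l])
                expected[i, j] = np.mean(members) > 0.30
        assert np.array_equal(mask.values, expected)

    def test_radius_below_one_cell_rejected(self):
        with pytest.raises(RasterError, match="one cell"):
            forest_neighborhood_mask(self.cover(np.ones((4, 4)), px=0.25), 5.0, 0.30)


class TestWaterQuality:
    def mask(self, slope, landform):
        s = make_grid(np.array([[slope]], dtype=np.int16), categorical=True)
        l = make_grid(np.array([[landform]], dtype=np.int16), categorical=True)
        return water_quality_mask(s, l).values[0, 0]

    @pytest.mark.parametrize(
        "slope,landform,expected",
        [
            (SLOPE_MODERATE, LANDFORM_UPLAND, 1),  # hillslope 20-35%
            (SLOPE_FLAT, LANDFORM_FLOODPLAIN, 1),  # floodplain
            (SLOPE_FLAT, LANDFORM_UPLAND, 0),
            (SLOPE_STEEP, LANDFORM_UPLAND, 0),
            (SLOPE_STEEP, LANDFORM_FLOODPLAIN, 1),
        ],
    )
    def test_rule(self, slope, landform, expected):
        assert self.mask(slope, landform) == expected

    def test_unknown_code_rejected(self):
        with pytest.raises(RasterError, match="unknown"):
            self.mask(9, LANDFORM_UPLAND)


@pytest.fixture(scope="module")
def cascade_state(small_bundle_module):
    return run_cascade(small_bundle_module)


@pytest.fixture(scope="module")
def small_bundle_module():
    return generate_bundle(SyntheticConfig(seed=7, n_coarse=8, fine_factor=8, mid_factor=2))


class TestApplyScenario:
    def test_full_mask_reproduces_constrained(self, cascade_state, small_bundle_module):
        b = small_bundle_module
        ones = Grid(
            np.ones(cascade_state.mid_geometry.shape, dtype=np.uint8),
            cascade_state.mid_geometry.transform, res_class="mid",
        )
        b2 = dataclasses.replace(b)
        b2.scenario_masks = {**b.scenario_masks, "everything": ones}
        pm = apply_scenario(
            ScenarioSpec("everything", "everything", "mid", "social"), cascade_state, b2
        )
        assert np.allclose(
            pm.availability.values, cascade_state.constrained.availability.values,
            atol=1e-12,
        )

    def test_empty_mask_zero_area(self, cascade_state, small_bundle_module):
        b = small_bundle_module
        zeros = Grid(
            np.zeros(cascade_state.mid_geometry.shape, dtype=np.uint8),
            cascade_state.mid_geometry.transform, res_class="mid",
        )
        b2 = dataclasses.replace(b)
        b2.scenario_masks = {**b.scenario_masks, "nothing": zeros}
        pm = apply_scenario(
            ScenarioSpec("nothing", "nothing", "mid", "social"), cascade_state, b2
        )
        assert area_summary(pm, cascade_state.areas) == 0.0

    def test_half_coverage_on_uniform_bundle_halves_area(self):
        # uniform availability: every coarse pixel fully available
        cfg = SyntheticConfig(
            seed=3, n_coarse=8, fine_factor=8, mid_factor=2,
            mean_tree_cover=80.0, tree_cover_spread=0.0, sd_scale=0.0,
            closed_fraction=1.0, open_fraction=0.0, walker_ui_scale=0.0,
            fire_rate=0.0, forest_fraction=0.0, cropland_fraction=0.0,
            water_fraction=0.0, builtup_fraction=0.0, bare_fraction=0.0,
            ice_fraction=0.0, wetland_fraction=0.0, peatland_fraction=0.0,
            oilpalm_fraction=0.0, albedo_negative_fraction=0.0,
        )
        b = generate_bundle(cfg)
        res = run_cascade(b)
        assert np.allclose(res.constrained.availability.values, 1.0)
        mid_shape = res.mid_geometry.shape
        east = np.zeros(mid_shape, dtype=np.uint8)
        east[:, mid_shape[1] // 2 :] = 1  # east half: identical band areas
        b.scenario_masks = {**b.scenario_masks, "east": Grid(
            east, res.mid_geometry.transform, res_class="mid"
        )}
        pm = apply_scenario(ScenarioSpec("east", "east", "mid", "social"), res, b)
        assert area_summary(pm, res.areas) == pytest.approx(
            0.5 * area_summary(res.constrained, res.areas), rel=1e-9
        )

    def test_every_scenario_bounded_by_constrained(self, cascade_state, small_bundle_module):
        maps = run_scenarios(cascade_state, small_bundle_module)
        base = cascade_state.constrained.availability.values
        for name, pm in maps.items():
            assert (pm.availability.values <= base + 1e-12).all(), name

    def test_country_mask_commutes_with_cascade(self, cascade_state, small_bundle_module):
        """Country-attribute masks are constant within coarse cells, so
        masking at mid then averaging equals masking the final map."""
        b = small_bundle_module
        m = b.config.mid_factor
        for name in ("high_rights", "secure_tenure", "restoration_goals"):
            pm = apply_scenario(
                ScenarioSpec(name, name, "mid", "social"), cascade_state, b
            )
            mid_mask = b.scenario_masks[name].values
            coarse_mask = mid_mask[::m, ::m]  # constant within each block
            direct = cascade_state.constrained.availability.values * coarse_mask
            assert np.allclose(pm.availability.values, direct, atol=1e-12), name

    def test_unknown_scenario_rejected(self, cascade_state, small_bundle_module):
        with pytest.raises(RasterError, match="unknown"):
            apply_scenario(
                ScenarioSpec("bogus", "bogus", "mid", "social"),
                cascade_state, small_bundle_module,
            )


class TestCombinationAreas:
    def test_singleton_equals_own_area(self, cascade_state, small_bundle_module):
        maps = run_scenarios(cascade_state, small_bundle_module)
        recs = combination_areas(maps, cascade_state.areas, [["high_rights"]])
        assert recs[0].area_Mha == pytest.approx(
            area_summary(maps["high_rights"], cascade_state.areas), rel=1e-12
        )

    def test_disjoint_maps_intersect_to_zero(self, cascade_state, small_bundle_module):
        b = small_bundle_module
        res = cascade_state
        shape = res.mid_geometry.shape
        west = np.zeros(shape, dtype=np.uint8)
        west[:, : shape[1] // 2] = 1
        east = 1 - west
        b2 = dataclasses.replace(b)
        b2.scenario_masks = {
            **b.scenario_masks,
            "west": Grid(west, res.mid_geometry.transform, res_class="mid"),
            "east": Grid(east, res.mid_geometry.transform, res_class="mid"),
        }
        maps = {
            "west": apply_scenario(ScenarioSpec("west", "west", "mid", "social"), res, b2),
            "east": apply_scenario(ScenarioSpec("east", "east", "mid", "social"), res, b2),
        }
        recs = combination_areas(maps, res.areas, [["west", "east"]])
        assert recs[0].area_Mha == pytest.approx(0.0, abs=1e-12)

    def test_nested_masks_intersect_to_innermost(self, cascade_state, small_bundle_module):
        b = small_bundle_module
        res = cascade_state
        shape = res.mid_geometry.shape
        masks = {}
        for k, frac in (("a", 1.0), ("b", 0.5), ("c", 0.25)):
            mvals = np.zeros(shape, dtype=np.uint8)
            mvals[:, : int(shape[1] * frac)] = 1
            masks[k] = Grid(mvals, res.mid_geometry.transform, res_class="mid")
        b2 = dataclasses.replace(b)
        b2.scenario_masks = {**b.scenario_masks, **masks}
        maps = {
            k: apply_scenario(ScenarioSpec(k, k, "mid", "social"), res, b2)
            for k in masks
        }
        recs = combination_areas(maps, res.areas, [["a", "b", "c"], ["c"]])
        assert recs[0].area_Mha == pytest.approx(recs[1].area_Mha, rel=1e-12)

    def test_intersections_shrink_with_members(self, cascade_state, small_bundle_module):
        maps = run_scenarios(cascade_state, small_bundle_module)
        names = [s.name for s in default_scenarios() if s.group != "base"]
        full = combination_areas(maps, cascade_state.areas, [names])[0]
        for drop in names:
            sub = [n for n in names if n != drop]
            parent = combination_areas(maps, cascade_state.areas, [sub])[0]
            assert full.area_Mha <= parent.area_Mha + 1e-12

    def test_empty_member_set_rejected(self, cascade_state, small_bundle_module):
        maps = run_scenarios(cascade_state, small_bundle_module)
        with pytest.raises(RasterError, match="at least one member"):
            combination_areas(maps, cascade_state.areas, [[]])
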