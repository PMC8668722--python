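"""Cross-realm covariates: nearest maps, distance layers, buffer stats,
nearest-terrestrial inheritance and landmasses — all against exhaustive
brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from mrsdm import (
    GridCell,
    MultiRealmConfig,
    RealmGrid,
    build_covariates,
    label_landmasses,
    marine_with_terrestrial,
    nearest_other_realm,
    terrestrial_with_marine,
)
from mrsdm.cross_realm import DISTANCE_FROM_LAND, DISTANCE_FROM_SEA, distance_variables
from mrsdm.errors import RealmDomainError
from mrsdm.grid import MARINE, TERRESTRIAL, great_circle_m

from helpers import (
    brute_buffer_stats,
    brute_isolation,
    brute_nearest,
    make_straight_coast_grid,
    random_realm_grid,
)


def line_grid():
    """1x3 grid: [terrestrial-only, both (coastal), marine-only]."""
    terr = np.array([[True, True, False]])
    mar = np.array([[False, True, True]])
    return RealmGrid(1, 3, origin_lon=0.0, origin_lat=45.0, cell_size=1 / 12,
                     terrestrial_valid=terr, marine_valid=mar)


class TestNearestOtherRealm:
    def test_coastal_zero_rule_on_line(self):
        g = line_grid()
        m = nearest_other_realm(g, TERRESTRIAL)
        assert m.nearest_cell(GridCell(0, 0)) == GridCell(0, 1)
        one_cell = great_circle_m(g.cell_center(GridCell(0, 0)), g.cell_center(GridCell(0, 1)))
        assert m.distance(GridCell(0, 0)) == pytest.approx(one_cell, rel=1e-12)
        assert m.nearest_cell(GridCell(0, 1)) == GridCell(0, 1)
        assert m.distance(GridCell(0, 1)) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("realm", [TERRESTRIAL, MARINE])
    def test_matches_brute_force(self, seed, realm):
        g = random_realm_grid(seed, max_side=20)
        got = nearest_other_realm(g, realm)
        expected = brute_nearest(g, realm)
        for cell, (near, dist) in expected.items():
            assert got.nearest_cell(cell) == near
            assert got.distance(cell) == pytest.approx(dist, rel=1e-12, abs=1e-9)

    def test_empty_other_realm_raises(self):
        terr = np.ones((3, 3), dtype=bool)
        g = RealmGrid(3, 3, 0.0, 45.0, 1 / 12, terrestrial_valid=terr)
        with pytest.raises(RealmDomainError):
            nearest_other_realm(g, TERRESTRIAL)


class TestDistanceVariables:
    def test_coastal_cells_zero_in_both_layers(self, small_world):
        maps = distance_variables(small_world)
        coastal = small_world.coastal
        for name in (DISTANCE_FROM_SEA, DISTANCE_FROM_LAND):
            layer = small_world.layers[name]
            assert np.all(layer.values[coastal] == 0.0)

    def test_two_cells_offshore_straight_coast(self):
        g = make_straight_coast_grid(n_land_rows=2, n_sea_rows=3)
        distance_variables(g)
        # coast (both-realm) row is row 1; marine row 3 is two cells south
        cell = GridCell(3, 2)
        two_cells = great_circle_m(g.cell_center(cell), g.cell_center(GridCell(1, 2)))
        got = g.layers[DISTANCE_FROM_LAND].values[3, 2]
        assert got == pytest.approx(two_cells, rel=1e-12)

    def test_layers_satisfy_map_invariants(self, small_world):
        maps = distance_variables(small_world)
        for realm, layer_name in ((TERRESTRIAL, DISTANCE_FROM_SEA), (MARINE, DISTANCE_FROM_LAND)):
            layer = small_world.layers[layer_name]
            m = maps[realm]
            mask = small_world.realm_valid(realm)
            vals = layer.values[mask]
            assert np.all(vals >= 0)
            assert np.array_equal(layer.values[mask], m.distance_m[mask])
            zero = mask & (m.distance_m == 0)
            assert np.array_equal(zero, small_world.coastal & mask)


class TestTerrestrialWithMarine:
    def test_hand_buffer_mean_and_variation(self):
        # terrestrial cell at col 0; marine cells at cols 1..3 with SST
        # 10, 12, 14; a large buffer samples all three.
        terr = np.array([[True, False, False, False]])
        mar = np.array([[False, True, True, True]])
        g = RealmGrid(1, 4, 0.0, 45.0, 1 / 12, terrestrial_valid=terr, marine_valid=mar)
        g.add_layer("sst", MARINE, np.array([[np.nan, 10.0, 12.0, 14.0]]))
        cfg = MultiRealmConfig(mmfd_m=100_000.0)
        cov = terrestrial_with_marine(g, cfg)
        row = cov.table.loc[(0, 0)]
        assert row["mean_sst"] == pytest.approx(12.0)
        assert row["sst_variation"] == pytest.approx(2.0)  # sample SD, n-1
        assert cov.n_sampled.loc[(0, 0)] == 3

    def test_degenerate_radius_samples_only_coast_cell(self):
        terr = np.array([[True, False, False, False]])
        mar = np.array([[False, True, True, True]])
        g = RealmGrid(1, 4, 0.0, 45.0, 1 / 12, terrestrial_valid=terr, marine_valid=mar)
        g.add_layer("sst", MARINE, np.array([[np.nan, 10.0, 12.0, 14.0]]))
        cov = terrestrial_with_marine(g, MultiRealmConfig(mmfd_m=1.0))
        row = cov.table.loc[(0, 0)]
        assert row["mean_sst"] == 10.0
        assert row["sst_variation"] == 0.0
        assert cov.n_sampled.loc[(0, 0)] == 1

    @pytest.mark.parametrize("seed", [5, 6])
    def test_matches_brute_force(self, seed):
        g = random_realm_grid(seed, max_side=18)
        cfg = MultiRealmConfig(mmfd_m=60_000.0)
        cov = terrestrial_with_marine(g, cfg)
        oracle = brute_buffer_stats(g, cfg.mmfd_m, "m_var")
        for cell, (n, mean, sd) in oracle.items():
            row = cov.table.loc[(cell.row, cell.col)]
            assert cov.n_sampled.loc[(cell.row, cell.col)] == n
            assert row["mean_m_var"] == pytest.approx(mean, rel=1e-12, nan_ok=True)
            assert row["m_var_variation"] == pytest.approx(sd, rel=1e-12, abs=1e-12, nan_ok=True)

    def test_enlarging_radius_never_shrinks_buffers(self):
        g = random_realm_grid(9, max_side=16)
        small = terrestrial_with_marine(g, MultiRealmConfig(mmfd_m=30_000.0))
        large = terrestrial_with_marine(g, MultiRealmConfig(mmfd_m=90_000.0))
        assert (large.n_sampled >= small.n_sampled).all()


class TestMarineWithTerrestrial:
    def test_single_candidate_inherited(self):
        terr = np.array([[True, False]])
        mar = np.array([[False, True]])
        g = RealmGrid(1, 2, 0.0, 45.0, 1 / 12, terrestrial_valid=terr, marine_valid=mar)
        g.add_layer("temperature", TERRESTRIAL, np.array([[21.0, np.nan]]))
        cov = marine_with_terrestrial(g)
        assert cov.table.loc[(0, 1), "nearest_temperature"] == 21.0

    def test_coastal_cell_inherits_its_own_values(self):
        g = line_grid()
        vals = np.array([[3.0, 7.0, np.nan]])
        g.add_layer("temperature", TERRESTRIAL, vals)
        cov = marine_with_terrestrial(g)
        assert cov.table.loc[(0, 1), "nearest_temperature"] == 7.0

    @pytest.mark.parametrize("seed", [12, 13])
    def test_matches_brute_force(self, seed):
        g = random_realm_grid(seed, max_side=18)
        cov = marine_with_terrestrial(g)
        oracle = brute_nearest(g, MARINE)
        terr_vals = g.layers["t_var"].values
        for cell, (near, _) in oracle.items():
            got = cov.table.loc[(cell.row, cell.col), "nearest_t_var"]
            expected = terr_vals[near.row, near.col]
            assert got == pytest.approx(expected, rel=1e-12, nan_ok=True)


class TestFocalRealmRows:
    @pytest.mark.parametrize("model_type", ["TerrOnly", "MarOnly", "TerrWithMar", "MarWithTerr"])
    def test_rows_only_for_focal_realm_cells(self, small_world, model_type):
        cfg = MultiRealmConfig(mmfd_m=40_000.0)
        cov = build_covariates(small_world, model_type, cfg)
        mask = small_world.realm_valid(cov.focal_realm)
        rows = cov.table.index.get_level_values("row").to_numpy()
        cols = cov.table.index.get_level_values("col").to_numpy()
        assert mask[rows, cols].all()
        assert len(cov.table) == int(mask.sum())


class TestLandmasses:
    def _grid_with_blobs(self):
        terr = np.zeros((8, 10), dtype=bool)
        terr[1, 1:4] = True                # 3-cell blob
        terr[5:6, 5:10] = True             # 5-cell blob
        mar = ~terr
        return RealmGrid(8, 10, 0.0, 55.0, 1 / 12, terrestrial_valid=terr, marine_valid=mar)

    def test_two_blobs_areas_and_isolation(self):
        g = self._grid_with_blobs()
        lm = label_landmasses(g)
        assert sorted(lm.table["n_cells"]) == [3, 5]
        oracle = brute_isolation(g, lm.labels)
        for lab, row in lm.table.iterrows():
            if np.isnan(row["isolation_m"]):
                assert np.isnan(oracle[lab])
            else:
                assert row["isolation_m"] == pytest.approx(oracle[lab], rel=1e-12)
        small = lm.table["n_cells"].idxmin()
        big = lm.table["n_cells"].idxmax()
        assert np.isfinite(lm.table.loc[small, "isolation_m"])
        assert np.isnan(lm.table.loc[big, "isolation_m"])

    def test_single_landmass_isolation_missing(self):
        terr = np.zeros((5, 5), dtype=bool)
        terr[1:3, 1:3] = True
        g = RealmGrid(5, 5, 0.0, 55.0, 1 / 12, terrestrial_valid=terr)
        lm = label_landmasses(g)
        assert len(lm.table) == 1
        assert np.isnan(lm.table["isolation_m"]).all()

    def test_equal_area_blobs_both_missing(self):
        # same rows (identical latitudes -> identical spherical areas)
        terr = np.zeros((5, 9), dtype=bool)
        terr[2, 0:3] = True
        terr[2, 6:9] = True
        g = RealmGrid(5, 9, 0.0, 55.0, 1 / 12, terrestrial_valid=terr)
        lm = label_landmasses(g)
        assert len(lm.table) == 2
        assert np.isnan(lm.table["isolation_m"]).all()

    def test_connectivity_choice(self):
        terr = np.zeros((4, 4), dtype=bool)
        terr[0, 0] = terr[1, 1] = True  # diagonal neighbours
        g = RealmGrid(4, 4, 0.0, 55.0, 1 / 12, terrestrial_valid=terr)
        assert len(label_landmasses(g, connectivity=8).table) == 1
        assert len(label_landmasses(g, connectivity=4).table) == 2

    def test_empty_mask_raises(self):
        g = RealmGrid(3, 3, 0.0, 55.0, 1 / 12, marine_valid=np.ones((3, 3), dtype=bool))
        with pytest.raises(RealmDomainError):
            label_landmasses(g)

    @pytest.mark.parametrize("seed", [21, 22])
    def test_isolation_matches_brute_force_random(self, seed):
        g = random_realm_grid(seed, max_side=15, with_layers=False)
        lm = label_landmasses(g)
        oracle = brute_isolation(g, lm.labels)
        for lab, row in lm.table.iterrows():
            if np.isnan(row["isolation_m"]):
                assert np.isnan(oracle[lab])
            else:
                assert row["isolation_m"] == pytest.approx(oracle[lab], rel=1e-12)
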