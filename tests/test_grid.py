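"""Grid model: coordinates, distance kernel, masks, and CSV round trips."""

import math
import subprocess

import numpy as np
import pytest
from scipy import integrate

from mrsdm import GridCell, RealmGrid, great_circle_m, haversine_m, load_grid, save_grid
from mrsdm.errors import AlignmentError, ConfigurationError, RealmDomainError
from mrsdm.grid import EARTH_RADIUS_M, load_grid_dir, save_layer_csv

from helpers import random_realm_grid


def make_grid(**kw):
    defaults = dict(n_rows=4, n_cols=5, origin_lon=-10.0, origin_lat=60.0, cell_size=1 / 12)
    defaults.update(kw)
    return RealmGrid(**defaults)


class TestCellCenter:
    def test_origin_cell(self):
        g = make_grid()
        assert g.cell_center(GridCell(0, 0)) == (-10.0, 60.0)

    def test_one_cell_east(self):
        g = make_grid()
        lon, lat = g.cell_center(GridCell(0, 1))
        assert lon == pytest.approx(-10.0 + 1 / 12, abs=1e-12)
        assert lat == 60.0

    def test_matches_affine_transform(self):
        # independent affine: [lon, lat]' = A @ [col, row]' + origin
        g = make_grid()
        A = np.array([[g.cell_size, 0.0], [0.0, -g.cell_size]])
        expected = A @ np.array([3, 2]) + np.array([g.origin_lon, g.origin_lat])
        assert g.cell_center(GridCell(2, 3)) == pytest.approx(tuple(expected), abs=1e-12)

    def test_out_of_bounds(self):
        g = make_grid()
        with pytest.raises(IndexError):
            g.cell_center(GridCell(4, 0))


class TestGreatCircle:
    def test_identical_points_zero(self):
        assert great_circle_m((12.3, 45.6), (12.3, 45.6)) == 0.0

    def test_one_degree_on_equator(self):
        # R * 1 degree in radians = 111,195 m
        assert great_circle_m((0.0, 0.0), (1.0, 0.0)) == pytest.approx(111_195, abs=1.0)

    def test_quarter_meridian(self):
        assert great_circle_m((0.0, 0.0), (0.0, 90.0)) == pytest.approx(
            math.pi * EARTH_RADIUS_M / 2.0, abs=1.0
        )

    def test_symmetry_and_nonnegativity(self, rng):
        pts = rng.uniform([-180, -89], [180, 89], size=(50, 2))
        for (lon1, lat1), (lon2, lat2) in zip(pts[:-1], pts[1:]):
            d = great_circle_m((lon1, lat1), (lon2, lat2))
            assert d >= 0
            assert d == pytest.approx(great_circle_m((lon2, lat2), (lon1, lat1)), abs=1e-6)

    def test_triangle_inequality_on_sphere(self, rng):
        pts = rng.uniform([-180, -85], [180, 85], size=(30, 2))
        a, b, c = pts[:10], pts[10:20], pts[20:]
        for p, q, r in zip(a, b, c):
            dpq = great_circle_m(tuple(p), tuple(q))
            dqr = great_circle_m(tuple(q), tuple(r))
            dpr = great_circle_m(tuple(p), tuple(r))
            assert dpr <= dpq + dqr + 1e-6

    def test_latitude_domain_error(self):
        with pytest.raises(RealmDomainError):
            great_circle_m((0.0, 91.0), (0.0, 0.0))

    def test_agrees_with_independent_geodesic_library(self, tmp_path, rng):
        """Spherical kernel vs geosphere: exact (same-sphere law of
        cosines) and within the spherical-vs-ellipsoidal band (distGeo)."""
        n = 1000
        lon1 = rng.uniform(-180, 180, 3 * n)
        lat1 = rng.uniform(-85, 85, 3 * n)
        lon2 = rng.uniform(-180, 180, 3 * n)
        lat2 = rng.uniform(-85, 85, 3 * n)
        d_sph = haversine_m(lon1, lat1, lon2, lat2)
        keep = np.nonzero((d_sph > 1_000) & (d_sph < 15_000_000))[0][:n]
        assert len(keep) == n
        pts = tmp_path / "pts.csv"
        out = tmp_path / "d.csv"
        np.savetxt(
            pts, np.c_[lon1[keep], lat1[keep], lon2[keep], lat2[keep]],
            delimiter=",", header="lon1,lat1,lon2,lat2", comments="",
        )
        script = (
            f'p <- read.csv("{pts}"); '
            f'ell <- geosphere::distGeo(p[,1:2], p[,3:4]); '
            f'sph <- geosphere::distCosine(p[,1:2], p[,3:4], r={EARTH_RADIUS_M!r}); '
            f'write.csv(data.frame(ell=ell, sph=sph), "{out}", row.names=FALSE)'
        )
        res = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        ref = np.loadtxt(out, delimiter=",", skiprows=1)
        rel_ell = np.abs(d_sph[keep] - ref[:, 0]) / ref[:, 0]
        rel_sph = np.abs(d_sph[keep] - ref[:, 1]) / ref[:, 1]
        assert rel_sph.max() < 1e-6          # same model, independent code
        assert rel_ell.max() < 6e-3          # sphere vs WGS84 geodesic
        assert rel_ell.mean() < 2.5e-3


class TestMasks:
    def test_coastal_is_conjunction(self):
        g = random_realm_grid(3)
        assert np.array_equal(g.coastal, g.terrestrial_valid & g.marine_valid)

    def test_layer_mask_subset_of_realm_mask(self):
        g = random_realm_grid(4)
        for layer in g.layers.values():
            assert not (layer.valid & ~g.realm_valid(layer.realm)).any()

    def test_unknown_realm_tag(self):
        g = make_grid()
        with pytest.raises(ConfigurationError):
            g.add_layer("x", "freshwater", np.zeros((4, 5)))


class TestCellArea:
    def test_matches_numerical_integration(self):
        g = make_grid(origin_lat=70.0, cell_size=0.5)
        for row in (0, 3):
            lat = g.origin_lat - row * g.cell_size
            integral, _ = integrate.quad(
                lambda phi: np.cos(np.radians(phi)), lat - 0.25, lat + 0.25
            )
            r_km = EARTH_RADIUS_M / 1000
            expected = r_km**2 * math.radians(0.5) * math.radians(1.0) * integral
            assert g.cell_area_km2(row) == pytest.approx(expected, rel=1e-10)

    def test_high_latitude_cells_smaller(self):
        g = make_grid(origin_lat=80.0)
        assert g.cell_area_km2(0) < g.cell_area_km2(3)


class TestGridIO:
    def test_round_trip_is_bit_stable(self, tmp_path):
        g = random_realm_grid(7)
        save_grid(g, tmp_path / "grid")
        g2 = load_grid_dir(tmp_path / "grid")
        assert g2.geo_meta() == g.geo_meta()
        assert np.array_equal(g2.terrestrial_valid, g.terrestrial_valid)
        assert np.array_equal(g2.marine_valid, g.marine_valid)
        assert set(g2.layers) == set(g.layers)
        for name, layer in g.layers.items():
            got = g2.layers[name]
            assert got.realm == layer.realm
            assert np.array_equal(got.valid, layer.valid)
            assert np.array_equal(
                got.values[got.valid], layer.values[layer.valid]
            )  # exact, not approx

    def test_two_single_layer_files(self, tmp_path):
        g = make_grid()
        vals = np.full((4, 5), np.nan)
        vals[:2] = 1.5
        g.add_layer("temp", "terrestrial", vals)
        sea = np.full((4, 5), np.nan)
        sea[2:] = 8.0
        g.add_layer("sst", "marine", sea)
        save_layer_csv(g, "temp", tmp_path / "temp.csv")
        save_layer_csv(g, "sst", tmp_path / "sst.csv")
        g2 = load_grid([tmp_path / "temp.csv", tmp_path / "sst.csv"])
        assert set(g2.layers) == {"temp", "sst"}
        assert g2.layers["temp"].realm == "terrestrial"
        assert g2.layers["sst"].realm == "marine"
        assert g2.terrestrial_valid.sum() == 10
        assert g2.marine_valid.sum() == 10

    def test_mismatched_cell_size_is_alignment_error(self, tmp_path):
        g1 = make_grid()
        g1.add_layer("a", "terrestrial", np.ones((4, 5)))
        g2 = make_grid(cell_size=0.25)
        g2.add_layer("b", "marine", np.ones((4, 5)))
        save_layer_csv(g1, "a", tmp_path / "a.csv")
        save_layer_csv(g2, "b", tmp_path / "b.csv")
        with pytest.raises(AlignmentError):
            load_grid([tmp_path / "a.csv", tmp_path / "b.csv"])

    def test_realm_tag_override_validates(self, tmp_path):
        g = make_grid()
        g.add_layer("a", "terrestrial", np.ones((4, 5)))
        save_layer_csv(g, "a", tmp_path / "a.csv")
        with pytest.raises(ConfigurationError):
            load_grid([tmp_path / "a.csv"], realm_tags={"a": "lunar"})
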