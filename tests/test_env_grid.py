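"""Grid preparation: stack loading, cropping, equal-area reprojection, masking."""

import numpy as np
import pytest

from conftest import make_grid, make_layer
from cryosdm import env_grid
from cryosdm.errors import (
    ConfigurationError,
    DataError,
    EmptyDomainError,
    GridConflictError,
)
from cryosdm.grid import (
    EARTH_RADIUS_KM,
    GEOGRAPHIC,
    LAEA_NORTH_POLE,
    EnvLayer,
    ScenarioStack,
    laea_forward,
    laea_inverse,
)
from cryosdm.raster_io import write_ascii_grid


def _stack_on(grid, arrays, names):
    return ScenarioStack(
        "present", [make_layer(grid, a, n) for a, n in zip(arrays, names)]
    )


class TestLoadStack:
    def test_consistent_rasters_share_grid(self, tmp_path, rng):
        grid = make_grid(10, 10, x0=0, y_top=60, cell=1.0)
        paths = []
        for name in ("a", "b"):
            lyr = make_layer(grid, rng.normal(size=(10, 10)), name)
            p = tmp_path / f"{name}.asc"
            write_ascii_grid(lyr, p)
            paths.append(p)
        stack = env_grid.load_stack(paths, ["a", "b"])
        assert stack.layer_names == ["a", "b"]
        assert stack["a"].grid.compatible(stack["b"].grid)

    def test_mismatched_dimensions_raise(self, tmp_path, rng):
        for name, shape in (("a", (10, 10)), ("b", (8, 10))):
            grid = make_grid(*shape, x0=0, y_top=60, cell=1.0)
            write_ascii_grid(
                make_layer(grid, rng.normal(size=shape), name), tmp_path / f"{name}.asc"
            )
        with pytest.raises(GridConflictError):
            env_grid.load_stack(
                [tmp_path / "a.asc", tmp_path / "b.asc"], ["a", "b"]
            )

    def test_nodata_cells_flagged_invalid(self, tmp_path):
        grid = make_grid(5, 5, x0=0, y_top=60, cell=1.0)
        vals = np.ones((5, 5))
        vals[(0, 2, 4), (1, 3, 0)] = -9999.0
        write_ascii_grid(
            EnvLayer("a", vals, vals != -9999.0, grid), tmp_path / "a.asc"
        )
        stack = env_grid.load_stack([tmp_path / "a.asc"], ["a"])
        assert stack["a"].valid_mask.sum() == 22
        assert not stack["a"].valid_mask[0, 1]

    def test_unreadable_file_names_path(self, tmp_path):
        with pytest.raises(Exception, match="nonexistent"):
            env_grid.load_stack([tmp_path / "nonexistent.asc"], ["a"])


class TestCropNorth:
    def test_all_retained_centres_north_of_cut(self, rng):
        grid = make_grid(36, 10, x0=0, y_top=90.0, cell=5.0)  # 90N..-90S
        stack = _stack_on(grid, [rng.normal(size=(36, 10))], ["t"])
        cropped = env_grid.crop_north(stack, 30.0)
        lats = env_grid.cell_centre_latitudes(cropped.grid)
        assert (lats >= 30.0).all()

    def test_lat_minus_90_is_identity(self, rng):
        grid = make_grid(10, 10, x0=0, y_top=60.0, cell=1.0)
        vals = rng.normal(size=(10, 10))
        stack = _stack_on(grid, [vals], ["t"])
        out = env_grid.crop_north(stack, -90.0)
        assert out.grid.shape == grid.shape
        np.testing.assert_array_equal(out["t"].values, vals)

    def test_lat_91_empties_domain(self, rng):
        grid = make_grid(10, 10, x0=0, y_top=60.0, cell=1.0)
        stack = _stack_on(grid, [rng.normal(size=(10, 10))], ["t"])
        with pytest.raises(EmptyDomainError):
            env_grid.crop_north(stack, 91.0)


class TestCellCentreLatitudes:
    def test_geographic_rows_give_row_centres(self):
        grid = make_grid(4, 3, x0=0, y_top=60.0, cell=10.0)
        lats = env_grid.cell_centre_latitudes(grid)
        np.testing.assert_allclose(lats[:, 0], [55, 45, 35, 25])

    def test_projected_pole_cell_is_90(self):
        # 2x2 LAEA grid centred on the pole: all 4 centres equidistant
        grid = make_grid(2, 2, x0=-50.0, y_top=50.0, cell=50.0, crs=LAEA_NORTH_POLE)
        lats = env_grid.cell_centre_latitudes(grid)
        assert (lats > 89.0).all()
        x, y = 0.0, 0.0
        _, lat = laea_inverse(x, y)
        assert lat == pytest.approx(90.0)

    def test_projection_round_trip_below_1e6_deg(self, rng):
        lon = rng.uniform(-180, 180, 500)
        lat = rng.uniform(0, 89.9, 500)
        x, y = laea_forward(lon, lat)
        lon2, lat2 = laea_inverse(x, y)
        dlon = np.abs((lon2 - lon + 180) % 360 - 180)
        assert np.max(np.abs(lat2 - lat)) < 1e-6
        assert np.max(dlon * np.cos(np.deg2rad(lat))) < 1e-6


class TestReprojectEqualArea:
    def test_identity_when_already_projected(self, rng):
        grid = make_grid(5, 5, x0=0, y_top=2000, cell=50.0, crs=LAEA_NORTH_POLE)
        vals = rng.normal(size=(5, 5))
        stack = _stack_on(grid, [vals], ["t"])
        out = env_grid.reproject_equal_area(stack, resolution_km=50.0)
        np.testing.assert_array_equal(out["t"].values, vals)

    def test_unknown_crs_rejected(self, rng):
        grid = make_grid(5, 5, x0=0, y_top=60, cell=1.0)
        stack = _stack_on(grid, [rng.normal(size=(5, 5))], ["t"])
        with pytest.raises(ConfigurationError):
            env_grid.reproject_equal_area(stack, target_crs="mercator")

    def test_area_preserved_within_5pct_of_spherical_oracle(self, rng):
        # valid blob on a 200x200 geographic grid between 45N and 85N
        grid = make_grid(200, 200, x0=-20.0, y_top=85.0, cell=0.2)
        vals = rng.normal(size=(200, 200))
        valid = np.zeros((200, 200), dtype=bool)
        valid[40:160, 30:170] = True
        stack = ScenarioStack(
            "present", [make_layer(grid, vals, "t", valid=valid)]
        )
        out = env_grid.reproject_equal_area(stack, resolution_km=15.0)
        got = out["t"].valid_mask.sum() * out.grid.cell_area_km2

        # oracle: spherical area of each valid source cell from its bounds
        rows, cols = np.where(valid)
        lat_top = grid.y_top - rows * grid.dy
        lat_bot = lat_top - grid.dy
        dlam = np.deg2rad(grid.dx)
        cell_areas = (
            EARTH_RADIUS_KM**2
            * dlam
            * (np.sin(np.deg2rad(lat_top)) - np.sin(np.deg2rad(lat_bot)))
        )
        expected = cell_areas.sum()
        assert abs(got - expected) / expected < 0.05

    def test_nodata_never_gains_values(self, rng):
        grid = make_grid(60, 120, x0=-60.0, y_top=80.0, cell=0.5)
        valid = rng.random((60, 120)) > 0.5
        stack = ScenarioStack(
            "present",
            [make_layer(grid, rng.normal(size=(60, 120)), "t", valid=valid)],
        )
        out = env_grid.reproject_equal_area(stack, resolution_km=30.0)
        # every valid target cell must map back to a valid source cell
        tgt = out.grid
        x, y = tgt.cell_centres()
        lon, lat = laea_inverse(x, y)
        lon = grid.x0 + np.mod(lon - grid.x0, 360.0)
        r, c = grid.xy_to_rowcol(lon, lat)
        inside = grid.inside(r, c)
        ok = np.zeros(tgt.shape, dtype=bool)
        ok[inside] = valid[np.clip(r, 0, 59), np.clip(c, 0, 119)][inside]
        assert not (out["t"].valid_mask & ~ok).any()


class TestStudyMask:
    def _inputs(self, depth, dist, sub, lat):
        grid = make_grid(1, 1, x0=0, y_top=lat + 0.5, cell=1.0)
        mk = lambda v, n: make_layer(grid, [[v]], n)
        lats = np.array([[lat]])
        return mk(depth, "depth"), mk(dist, "dist"), mk(sub, "sub"), lats

    @pytest.mark.parametrize(
        "depth,dist,sub,lat,expected",
        [
            (50.0, 200.0, 1.0, 45.0, True),  # shallow rocky cell
            (500.0, 5.0, 1.0, 60.0, True),  # deep but near shore
            (50.0, 200.0, 0.0, 45.0, False),  # depositional substrate
            (50.0, 200.0, 1.0, 25.0, False),  # south of study area
            (500.0, 200.0, 1.0, 60.0, False),  # deep and offshore
            (0.0, 200.0, 1.0, 30.0, True),  # boundary: inclusive both ends
            (100.0, 200.0, 1.0, 30.0, True),
        ],
    )
    def test_inclusion_rules(self, depth, dist, sub, lat, expected):
        d, s, b, lats = self._inputs(depth, dist, sub, lat)
        mask = env_grid.build_study_mask(d, s, b, lats)
        assert bool(mask.included[0, 0]) is expected

    def test_unknown_substrate_code_rejected(self):
        d, s, b, lats = self._inputs(50.0, 5.0, 7.0, 45.0)
        with pytest.raises(DataError):
            env_grid.build_study_mask(d, s, b, lats)

    def test_masking_is_monotone_in_thresholds(self, rng):
        grid = make_grid(20, 20, x0=0, y_top=80.0, cell=1.0)
        depth = make_layer(grid, rng.uniform(0, 300, (20, 20)), "depth")
        dist = make_layer(grid, rng.uniform(0, 60, (20, 20)), "dist")
        sub = make_layer(grid, (rng.random((20, 20)) > 0.4).astype(float), "sub")
        lats = env_grid.cell_centre_latitudes(grid)
        m1 = env_grid.build_study_mask(depth, dist, sub, lats,
                                       depth_max_m=100, shore_km=10)
        for dmax, skm in [(150, 10), (100, 25), (300, 50)]:
            m2 = env_grid.build_study_mask(depth, dist, sub, lats,
                                           depth_max_m=dmax, shore_km=skm)
            assert not (m1.included & ~m2.included).any()

    def test_area_equals_count_times_cell_area(self, rng):
        grid = make_grid(10, 10, x0=0, y_top=500, cell=50.0, crs=LAEA_NORTH_POLE)
        depth = make_layer(grid, rng.uniform(0, 200, (10, 10)), "depth")
        dist = make_layer(grid, rng.uniform(0, 30, (10, 10)), "dist")
        sub = make_layer(grid, np.ones((10, 10)), "sub")
        lats = env_grid.cell_centre_latitudes(grid)
        mask = env_grid.build_study_mask(depth, dist, sub, lats)
        assert mask.area_km2() == mask.n_cells * 2500.0
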