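"""Windowed rugosity, PCA plane fitting, slope/aspect and the multiscale engine."""

import numpy as np
import pandas as pd
import pytest

from tinrugosity import (
    DegenerateGeometryError,
    TriangleMesh,
    WindowSpec,
    aspect,
    extract_window,
    fit_pca_plane,
    multiscale_features,
    projected_area,
    rugosity,
    slope,
    surface_area,
    window_features,
)
from tinrugosity import synthetic
from tinrugosity.gis import write_ascii_grid, write_feature_csv
from .conftest import grid_mesh, rotation_z


class TestExtractWindow:
    def test_window_covering_whole_mesh(self, grid5):
        subset = extract_window(grid5, WindowSpec((1.0, 1.0), 10.0))
        assert subset.n_triangles == grid5.n_triangles
        assert subset.n_vertices == grid5.n_vertices

    def test_window_inside_one_big_triangle_is_empty(self):
        mesh = TriangleMesh(
            vertices=np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0.0]]),
            triangles=np.array([[0, 1, 2]]),
        )
        subset = extract_window(mesh, WindowSpec((2.0, 2.0), 1.0))
        assert subset.n_triangles == 0
        assert subset.n_vertices == 0

    def test_matches_exhaustive_all_inside_test(self):
        """Indexed query equals brute-force three-corners-inside filter."""
        mesh = grid_mesh(4, spacing=1.0)
        spec = WindowSpec((1.5, 1.5), 1.5)
        fast = extract_window(mesh, spec)
        slow = extract_window(mesh, spec, exhaustive=True)
        np.testing.assert_array_equal(fast.triangle_indices, slow.triangle_indices)
        np.testing.assert_array_equal(fast.vertex_indices, slow.vertex_indices)
        # brute force written out longhand
        half = spec.width / 2
        inside = np.all(
            np.abs(mesh.vertices[mesh.triangles][:, :, :2]
                   - np.array(spec.centre)) <= half + 1e-15,
            axis=(1, 2),
        )
        np.testing.assert_array_equal(fast.triangle_indices, np.flatnonzero(inside))

    def test_boundary_vertices_count_as_inside(self):
        """The rectangle is closed: corner triangles exactly on it are IN."""
        mesh = grid_mesh(3, spacing=1.0)
        subset = extract_window(mesh, WindowSpec((1.0, 1.0), 2.0))
        assert subset.n_triangles == mesh.n_triangles

    def test_oriented_window(self):
        """A rotated window membership is evaluated in rotated coordinates."""
        mesh = grid_mesh(11, spacing=0.5)
        spec = WindowSpec((2.5, 2.5), width=1.0, length=4.0, orientation=45.0)
        subset = extract_window(mesh, spec)
        slow = extract_window(mesh, spec, exhaustive=True)
        np.testing.assert_array_equal(subset.triangle_indices, slow.triangle_indices)
        assert 0 < subset.n_triangles < mesh.n_triangles

    def test_index_and_exhaustive_agree_on_random_windows(self):
        mesh = synthetic.noise_field(sigma=0.1, extent=(4, 4), resolution=0.25, seed=2)
        rng = np.random.default_rng(8)
        for _ in range(10):
            spec = WindowSpec(
                tuple(rng.uniform(-1.5, 1.5, 2)),
                width=rng.uniform(0.4, 2.0),
                length=rng.uniform(0.4, 2.0),
                orientation=rng.uniform(0, 360),
            )
            fast = extract_window(mesh, spec)
            slow = extract_window(mesh, spec, exhaustive=True)
            np.testing.assert_array_equal(fast.triangle_indices, slow.triangle_indices)


class TestAreas:
    def test_flat_unit_window_area(self, unit_square_mesh):
        subset = extract_window(unit_square_mesh, WindowSpec((0.5, 0.5), 1.0))
        assert surface_area(subset, unit_square_mesh) == pytest.approx(1.0)

    def test_empty_subset_zero_area(self, unit_square_mesh):
        subset = extract_window(unit_square_mesh, WindowSpec((50.0, 50.0), 1.0))
        assert surface_area(subset, unit_square_mesh) == 0.0

    def test_sawtooth_surface_area(self):
        """45-degree sawtooth over the unit window has area sqrt(2)."""
        mesh = grid_mesh(11, spacing=0.1, z_fn=lambda e, n: 0.05 - np.abs((e % 0.2) - 0.1))
        subset = extract_window(mesh, WindowSpec((0.5, 0.5), 1.0))
        assert surface_area(subset, mesh) == pytest.approx(np.sqrt(2), rel=1e-9)

    def test_whole_mesh_window_equals_total_area(self):
        from tinrugosity import triangle_areas

        mesh = synthetic.noise_field(sigma=0.2, extent=(3, 3), resolution=0.25, seed=4)
        subset = extract_window(mesh, WindowSpec((0.0, 0.0), 100.0))
        assert surface_area(subset, mesh) == pytest.approx(triangle_areas(mesh).sum())


class TestPCAPlane:
    def test_horizontal_plane(self):
        rng = np.random.default_rng(0)
        pts = np.column_stack([rng.uniform(0, 1, (50, 2)), np.full(50, 2.0)])
        basis = fit_pca_plane(pts)
        np.testing.assert_allclose(basis.normal, [0, 0, 1], atol=1e-12)

    def test_45_degree_plane_closed_form(self):
        """Points on z = E have normal (-1, 0, 1)/sqrt(2)."""
        rng = np.random.default_rng(1)
        en = rng.uniform(-1, 1, (100, 2))
        pts = np.column_stack([en, en[:, 0]])
        basis = fit_pca_plane(pts)
        np.testing.assert_allclose(basis.normal, np.array([-1, 0, 1]) / np.sqrt(2), atol=1e-9)

    def test_noisy_plane_normal_within_one_degree(self):
        rng = np.random.default_rng(42)
        en = rng.uniform(-1, 1, (500, 2))
        z = 0.3 * en[:, 0] - 0.2 * en[:, 1] + rng.normal(0, 0.01, 500)
        basis = fit_pca_plane(np.column_stack([en, z]))
        true_n = np.array([-0.3, 0.2, 1.0])
        true_n /= np.linalg.norm(true_n)
        angle = np.degrees(np.arccos(np.clip(basis.normal @ true_n, -1, 1)))
        assert angle < 1.0

    def test_orthonormal_descending(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((200, 3)) * [3.0, 2.0, 0.1]
        basis = fit_pca_plane(pts)
        np.testing.assert_allclose(basis.components @ basis.components.T, np.eye(3), atol=1e-9)
        assert basis.eigenvalues[0] >= basis.eigenvalues[1] >= basis.eigenvalues[2]
        assert basis.normal[2] >= 0

    def test_collinear_raises(self):
        pts = np.outer(np.arange(10.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometryError):
            fit_pca_plane(pts)

    def test_vertical_plane_warns_and_orients_north(self):
        pts = np.column_stack(
            [np.zeros(50), np.tile(np.linspace(0, 1, 10), 5), np.repeat(np.linspace(0, 1, 5), 10)]
        )
        with pytest.warns(UserWarning, match="vertical"):
            basis = fit_pca_plane(pts)
        assert basis.normal[1] >= 0


class TestProjectedArea:
    def test_flat_subset_onto_horizontal(self, unit_square_mesh):
        subset = extract_window(unit_square_mesh, WindowSpec((0.5, 0.5), 1.0))
        a_s = surface_area(subset, unit_square_mesh)
        assert projected_area(subset, unit_square_mesh, [0, 0, 1]) == pytest.approx(a_s)

    def test_vertical_triangle_contributes_zero(self):
        mesh = TriangleMesh(
            vertices=np.array([[0, 0, 0], [1, 0, 0], [0.5, 0, 1.0]]),
            triangles=np.array([[0, 1, 2]]),
        )
        subset = extract_window(mesh, WindowSpec((0.5, 0.0), 2.0))
        assert subset.n_triangles == 1
        assert projected_area(subset, mesh, [0, 0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_tilted_patch_cosine_foreshortening(self):
        """A 30-degree planar patch projects to A_s * cos(30)."""
        grad = np.tan(np.radians(30.0))
        mesh = grid_mesh(9, spacing=0.25, z_fn=lambda e, n: grad * e)
        subset = extract_window(mesh, WindowSpec((1.0, 1.0), 1.5))
        a_s = surface_area(subset, mesh)
        a_p = projected_area(subset, mesh, [0, 0, 1])
        assert a_p == pytest.approx(a_s * np.cos(np.radians(30.0)), rel=1e-12)

    def test_never_exceeds_surface_area(self):
        rng = np.random.default_rng(3)
        mesh = synthetic.noise_field(sigma=0.3, extent=(3, 3), resolution=0.2, seed=1)
        subset = extract_window(mesh, WindowSpec((0, 0), 2.0))
        a_s = surface_area(subset, mesh)
        for _ in range(10):
            n = rng.standard_normal(3)
            assert projected_area(subset, mesh, n / np.linalg.norm(n)) <= a_s + 1e-12


class TestRugosity:
    def test_flat_terrain_both_projections_one(self, grid5):
        subset = extract_window(grid5, WindowSpec((1.0, 1.0), 2.0))
        for proj in ("pca", "horizontal"):
            assert rugosity(subset, grid5, projection=proj)["rugosity"] == pytest.approx(
                1.0, abs=1e-12
            )

    @pytest.mark.parametrize("alpha", [15.0, 30.0, 45.0, 60.0])
    def test_decoupling_on_inclined_planes(self, alpha):
        """PCA projection gives 1 on any plane; horizontal gives 1/cos(slope)."""
        mesh = synthetic.inclined(slope_deg=alpha, facing_deg=30.0,
                                  extent=(2, 2), resolution=0.1)
        subset = extract_window(mesh, WindowSpec((0, 0), 1.0))
        r_pca = rugosity(subset, mesh, projection="pca")["rugosity"]
        r_ne = rugosity(subset, mesh, projection="horizontal")["rugosity"]
        assert r_pca == pytest.approx(1.0, abs=1e-9)
        assert r_ne == pytest.approx(1.0 / np.cos(np.radians(alpha)), abs=1e-9)

    def test_too_few_triangles_is_missing_not_error(self, unit_square_mesh):
        subset = extract_window(unit_square_mesh, WindowSpec((0.5, 0.5), 1.0))
        out = rugosity(subset, unit_square_mesh, min_triangles=10)
        assert np.isnan(out["rugosity"])
        assert out["reason"] == "too_few_triangles"

    def test_area_weighted_pca_option(self):
        mesh = synthetic.peak_trough(extent=(4, 4), resolution=0.1)
        rec_v = window_features(mesh, WindowSpec((0, 0.7), 1.0), pca_weighting="vertex")
        rec_a = window_features(mesh, WindowSpec((0, 0.7), 1.0), pca_weighting="area")
        assert rec_a.rugosity_pca == pytest.approx(rec_v.rugosity_pca, rel=0.02)
        assert rec_a.rugosity_pca != rec_v.rugosity_pca  # genuinely different fits


class TestSlopeAspect:
    def _basis(self, normal):
        from tinrugosity import PCABasis

        n = np.asarray(normal, dtype=float)
        n /= np.linalg.norm(n)
        e1 = np.cross(n, [0, 0, 1.0])
        if np.linalg.norm(e1) < 1e-12:
            e1 = np.array([1.0, 0, 0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(n, e1)
        return PCABasis(
            components=np.stack([e1, e2, n]),
            eigenvalues=np.array([2.0, 1.0, 0.0]),
            centroid=np.zeros(3),
        )

    @pytest.mark.parametrize(
        "normal, expected",
        [([0, 0, 1], 0.0), ([1, 0, 1], 45.0), ([0.6, 0, 0.8], np.degrees(np.arccos(0.8)))],
    )
    def test_slope_closed_forms(self, normal, expected):
        assert slope(self._basis(normal)) == pytest.approx(expected, abs=1e-9)

    def test_aspect_north_east_conventions(self):
        psi, n, e = aspect(self._basis([0, 0.5, 0.866]))
        assert psi == pytest.approx(0.0, abs=1e-9)
        assert (n, e) == (pytest.approx(1.0), pytest.approx(0.0, abs=1e-12))
        psi_e, _, east = aspect(self._basis([0.5, 0, 0.866]))
        assert psi_e == pytest.approx(90.0)
        assert east == pytest.approx(1.0)

    def test_aspect_southwest_quadrant(self):
        psi, n, e = aspect(self._basis([-0.5, -0.5, 1 / np.sqrt(2)]))
        assert psi == pytest.approx(-135.0)
        assert n == pytest.approx(-np.sqrt(2) / 2)
        assert e == pytest.approx(-np.sqrt(2) / 2)

    def test_zero_slope_aspect_missing(self):
        psi, n, e = aspect(self._basis([0, 0, 1]))
        assert np.isnan(psi) and np.isnan(n) and np.isnan(e)

    def test_northness_eastness_unit_norm(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            v = rng.standard_normal(3)
            v[2] = abs(v[2]) + 0.1
            psi, n, e = aspect(self._basis(v))
            assert n * n + e * e == pytest.approx(1.0, abs=1e-9)


class TestMultiscale:
    def test_composition_oracle_single_centre(self):
        """multiscale_features row equals the single-window pipeline exactly."""
        mesh = synthetic.peak_trough(extent=(4, 4), resolution=0.1)
        df = multiscale_features(mesh, [1.0], centres="grid", stride=5.0)[0]
        assert len(df) == 1
        rec = window_features(
            mesh, WindowSpec((df.centre_e[0], df.centre_n[0]), 1.0)
        )
        for field in ("area_surface", "rugosity_pca", "rugosity_ne", "slope_deg",
                      "aspect_deg", "northness", "eastness"):
            a, b = df[field][0], getattr(rec, field)
            assert (np.isnan(a) and np.isnan(b)) or a == b

    def test_flat_mesh_all_scales(self):
        mesh = grid_mesh(9, spacing=0.25)
        frames = multiscale_features(mesh, [1.0, 1.5], centres="every_vertex")
        for df in frames:
            defined = df[df.reason.str.startswith(("ok", "zero_slope"))]
            assert len(defined) > 0
            np.testing.assert_allclose(defined.rugosity_pca, 1.0, atol=1e-9)
            np.testing.assert_allclose(defined.slope_deg, 0.0, atol=1e-9)
            assert defined.aspect_deg.isna().all()

    def test_sinusoid_variance_shrinks_with_window_size(self):
        """Windows of 1..4 wavelengths smooth the rugosity field monotonically."""
        mesh = synthetic.sinusoid(amplitude=0.1, wavelength=0.5,
                                  extent=(5, 5), resolution=0.05)
        frames = multiscale_features(
            mesh, [0.5, 1.0, 1.5, 2.0], centres="grid", stride=0.25
        )
        variances = [df.rugosity_ne.var() for df in frames]
        assert all(np.isfinite(v) for v in variances)
        assert variances == sorted(variances, reverse=True)

    def test_rotation_equivariance(self):
        """Yaw by beta: R and slope unchanged, aspect shifted by -beta."""
        mesh = synthetic.peak_trough(extent=(4, 4), resolution=0.1)
        beta = 50.0
        rot = rotation_z(beta)
        moved = TriangleMesh(vertices=mesh.vertices @ rot.T, triangles=mesh.triangles)
        centre = np.array([0.3, 0.8])
        rec0 = window_features(mesh, WindowSpec(tuple(centre), 1.0))
        c_rot = rot[:2, :2] @ centre
        rec1 = window_features(moved, WindowSpec(tuple(c_rot), 1.0, orientation=beta))
        assert rec1.rugosity_pca == pytest.approx(rec0.rugosity_pca, abs=1e-9)
        assert rec1.rugosity_ne == pytest.approx(rec0.rugosity_ne, abs=1e-9)
        assert rec1.slope_deg == pytest.approx(rec0.slope_deg, abs=1e-9)
        shift = (rec1.aspect_deg - (rec0.aspect_deg - beta)) % 360.0
        assert min(shift, 360 - shift) == pytest.approx(0.0, abs=1e-6)


class TestExport:
    def test_csv_round_trip(self, tmp_path, grid5):
        df = multiscale_features(grid5, [1.0], centres="grid", stride=0.5)[0]
        out = tmp_path / "features.csv"
        write_feature_csv(df, out)
        back = pd.read_csv(out)
        assert list(back.columns) == list(df.columns)
        assert len(back) == len(df)

    def test_ascii_grid_header_and_nodata(self, tmp_path, grid5):
        df = multiscale_features(grid5, [1.0], centres="grid", stride=0.5)[0]
        out = tmp_path / "rugosity.asc"
        write_ascii_grid(df, "rugosity_pca", out, cellsize=0.5)
        text = out.read_text().splitlines()
        assert text[0].startswith("ncols")
        assert any(l.startswith("NODATA_value -9999") for l in text)
        header = dict(l.split() for l in text[:6])
        grid = np.loadtxt(out, skiprows=6)
        assert grid.shape == (int(header["nrows"]), int(header["ncols"]))
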