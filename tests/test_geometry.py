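"""Axes, slicing, rasterization, exclusion rules and scar labeling."""

import numpy as np
import pytest
import trimesh

from lvscar.geometry import (
    AnatomicalMask,
    GeometryError,
    SliceContours,
    SliceSample,
    compute_axes,
    filter_slice,
    label_slice,
    points_inside_mesh,
    rasterize,
    slice_mesh,
    slice_samples,
)

from conftest import annulus_mask, circle_polyline, spheroid_shell


def rotation_matrix(axis, angle):
    ax = np.asarray(axis, float)
    ax = ax / np.linalg.norm(ax)
    K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


class TestComputeAxes:
    def test_prolate_spheroid_major_axis(self):
        mesh = spheroid_shell()
        frame = compute_axes(mesh)
        assert abs(abs(frame.long_axis @ np.array([1.0, 0, 0])) - 1.0) < 1e-9
        assert frame.length == pytest.approx(90.0, abs=1e-6)

    def test_rotated_spheroid_recovers_rotated_axis(self):
        R = rotation_matrix([1.0, 2.0, 0.5], 0.8)
        mesh = spheroid_shell(rotation=R)
        frame = compute_axes(mesh)
        expected = R @ np.array([1.0, 0.0, 0.0])
        assert abs(abs(frame.long_axis @ expected) - 1.0) < 1e-6

    def test_sphere_degenerate_is_deterministic_and_warns(self):
        mesh = spheroid_shell(semi_axes_epi=(30.0,) * 3, semi_axes_endo=(25.0,) * 3)
        with pytest.warns(UserWarning, match="degenerate"):
            f1 = compute_axes(mesh)
        with pytest.warns(UserWarning):
            f2 = compute_axes(mesh)
        assert np.allclose(f1.long_axis, f2.long_axis)
        assert np.linalg.norm(f1.long_axis) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_planar_cloud_raises(self):
        pts = np.column_stack([np.random.default_rng(0).random((10, 2)), np.zeros(10)])
        mesh = spheroid_shell()
        mesh.epi_vertices = pts
        with pytest.raises(GeometryError, match="rank"):
            compute_axes(mesh)

    def test_valve_points_orient_axis_toward_base(self, scarred_mesh):
        frame = compute_axes(scarred_mesh)
        # valve markers sit on the basal rim: base end must be nearer to them
        vp = scarred_mesh.valve_points.mean(axis=0)
        assert np.linalg.norm(vp - frame.base_point) < np.linalg.norm(vp - frame.apex_point)


class TestSliceMesh:
    def test_default_protocol_yields_25_planes(self, scarred_mesh):
        frame = compute_axes(scarred_mesh)
        contours = slice_mesh(scarred_mesh, frame)
        assert len(contours) == 25

    def test_first_plane_at_20_percent_above_apex(self, scarred_mesh):
        frame = compute_axes(scarred_mesh)
        contours = slice_mesh(scarred_mesh, frame)
        d = (contours[0].plane_origin - frame.apex_point) @ frame.long_axis
        assert d == pytest.approx(0.20 * frame.length, abs=1e-9)

    def test_cylinder_slices_are_concentric_circle_pairs(self):
        epi = trimesh.creation.cylinder(radius=30.0, height=100.0, sections=128)
        endo = trimesh.creation.cylinder(radius=20.0, height=80.0, sections=128)
        mesh = spheroid_shell()
        mesh.epi_vertices = np.asarray(epi.vertices, float)
        mesh.epi_faces = np.asarray(epi.faces)
        mesh.endo_vertices = np.asarray(endo.vertices, float)
        mesh.endo_faces = np.asarray(endo.faces)
        frame = compute_axes(mesh)
        contours = slice_mesh(mesh, frame, apex_offset=0.0)
        for c in contours[5:20]:  # mid-height planes cut both cylinders
            assert len(c.epi_contours) == 1 and len(c.endo_contours) == 1
            r_epi = np.linalg.norm(c.epi_contours[0], axis=1)
            r_endo = np.linalg.norm(c.endo_contours[0], axis=1)
            assert np.allclose(r_epi, 30.0, atol=0.05)
            assert np.allclose(r_endo, 20.0, atol=0.05)

    def test_plane_missing_mesh_is_empty_and_invalid(self):
        mesh = spheroid_shell()
        frame = compute_axes(mesh)
        # a short endo means basal planes miss it; an absurd offset misses epi
        far = SliceContours(
            plane_origin=frame.base_point + 500 * frame.long_axis,
            plane_normal=frame.long_axis,
            epi_contours=[], endo_contours=[],
        )
        assert far.is_empty

    def test_seeded_jitter_moves_planes_within_half_spacing(self, plain_mesh):
        frame = compute_axes(plain_mesh)
        fixed = slice_mesh(plain_mesh, frame)
        jit = slice_mesh(plain_mesh, frame, jitter_rng=np.random.default_rng(0))
        spacing = 0.8 * frame.length / 24
        for a, b in zip(fixed, jit):
            d = abs((a.plane_origin - b.plane_origin) @ frame.long_axis)
            assert d <= 0.5 * spacing + 1e-9


class TestRasterize:
    def _contours(self, epi, endo):
        return SliceContours(
            plane_origin=np.zeros(3), plane_normal=np.array([0.0, 0, 1]),
            epi_contours=epi, endo_contours=endo,
        )

    def test_annulus_wall_thickness_one_pixel_of_analytic(self):
        c = self._contours([circle_polyline(30.0)], [circle_polyline(20.0)])
        mask = rasterize(c)
        assert mask.grid.shape == (256, 256)
        # radial thickness along many rays from the grid center
        cx = cy = 127.5
        for ang in np.linspace(0, 2 * np.pi, 24, endpoint=False):
            r = np.arange(0, 45, 0.25)
            cols = np.rint(cx + r * np.cos(ang)).astype(int)
            rows = np.rint(cy + r * np.sin(ang)).astype(int)
            vals = mask.grid[rows, cols]
            thickness = vals.sum() * 0.25
            assert abs(thickness - 10.0) <= 1.0

    def test_annulus_area_within_discretization_bound(self):
        c = self._contours([circle_polyline(30.0)], [circle_polyline(20.0)])
        mask = rasterize(c)
        analytic = np.pi * (30.0**2 - 20.0**2)
        perimeter = 2 * np.pi * (30.0 + 20.0)
        assert abs(mask.foreground_count - analytic) <= 2 * perimeter

    def test_annulus_matches_bruteforce_membership(self):
        c = self._contours([circle_polyline(30.0)], [circle_polyline(20.0)])
        mask = rasterize(c)
        xs, ys = np.meshgrid(np.arange(256.0), np.arange(256.0))
        r = np.hypot(xs - 127.5, ys - 127.5)
        oracle = (r <= 30.0) & (r >= 20.0)
        # disagreement only possible in the boundary shell of the polygonal
        # approximation of the circles
        mismatch = (mask.grid.astype(bool) != oracle)
        near_boundary = (np.abs(r - 30.0) < 0.8) | (np.abs(r - 20.0) < 0.8)
        assert not (mismatch & ~near_boundary).any()

    def test_epi_only_gives_filled_disc(self):
        c = self._contours([circle_polyline(10.0)], [])
        mask = rasterize(c)
        assert abs(mask.foreground_count - np.pi * 100.0) <= 2 * (2 * np.pi * 10.0)
        # center pixel is foreground (no cavity)
        assert mask.grid[128, 128] == 1

    def test_square_pixel_count_matches_analytic(self):
        sq = np.array([[0.0, 0], [10, 0], [10, 10], [0, 10], [0, 0]])
        c = self._contours([sq], [])
        mask = rasterize(c)
        # centroid (5,5) maps to the grid center; pixel centers then sit at
        # half-integer offsets, so exactly the 10x10 interior centers are in
        assert mask.foreground_count == 100

    def test_contour_exceeding_fov_raises(self):
        c = self._contours([circle_polyline(200.0)], [])
        with pytest.raises(GeometryError, match="field of view"):
            rasterize(c)

    def test_no_epi_contour_raises(self):
        c = self._contours([], [])
        with pytest.raises(GeometryError):
            rasterize(c)


class TestFilterSlice:
    def _sample(self, n_fg, self_x=False, valve=False):
        grid = np.zeros((256, 256), dtype=np.uint8)
        grid.flat[:n_fg] = 1
        contours = SliceContours(
            plane_origin=np.zeros(3), plane_normal=np.array([0.0, 0, 1]),
            epi_contours=[circle_polyline(10.0)], endo_contours=[],
            self_intersecting=self_x, hits_valve=valve,
        )
        return SliceSample(mask=AnatomicalMask(grid=grid), label=0, contours=contours)

    def test_49_pixels_excluded_50_retained(self):
        assert filter_slice(self._sample(49)).reason == "too_small"
        assert not filter_slice(self._sample(49)).valid
        kept = filter_slice(self._sample(50))
        assert kept.valid and kept.reason == "none"

    def test_figure_eight_contour_excluded(self):
        out = filter_slice(self._sample(500, self_x=True))
        assert not out.valid and out.reason == "self_intersecting"

    def test_valve_hit_excluded(self):
        out = filter_slice(self._sample(500, valve=True))
        assert not out.valid and out.reason == "valve"

    def test_idempotent_and_order_independent(self):
        s = self._sample(10, self_x=True, valve=True)  # fails three rules
        once = filter_slice(s)
        twice = filter_slice(once)
        assert not once.valid and not twice.valid
        assert once.reason == twice.reason
        # excluded regardless of which reason is reported
        assert once.reason in {"self_intersecting", "valve", "too_small"}


class TestLabelSlice:
    def _planes(self, n=25):
        return [
            SliceContours(
                plane_origin=np.array([0.0, 0.0, float(k)]),
                plane_normal=np.array([0.0, 0.0, 1.0]),
                epi_contours=[], endo_contours=[], slice_index=k,
            )
            for k in range(n)
        ]

    def test_no_scar_mesh_means_all_zero(self):
        assert all(label_slice(c, None) == 0 for c in self._planes())

    def test_sphere_spanning_planes_10_to_14(self):
        scar = trimesh.creation.icosphere(subdivisions=2, radius=2.5)
        scar.apply_translation([0, 0, 12.0])
        labels = [label_slice(c, scar) for c in self._planes()]
        assert labels == [1 if 10 <= k <= 14 else 0 for k in range(25)]

    def test_agrees_with_surface_point_oracle(self):
        rng = np.random.default_rng(3)
        scar = trimesh.creation.icosphere(subdivisions=3, radius=3.6)
        scar.apply_translation([1.0, -2.0, 8.3])
        pts, _ = trimesh.sample.sample_surface(scar, 10_000, seed=9)
        for c in self._planes():
            d = (pts - c.plane_origin) @ c.plane_normal
            oracle = int(d.min() <= 0 <= d.max())
            assert label_slice(c, scar) == oracle

    def test_open_scar_mesh_raises_with_boundary_count(self):
        scar = trimesh.creation.icosphere(subdivisions=1)
        scar = trimesh.Trimesh(scar.vertices, scar.faces[:-1], process=False)
        with pytest.raises(GeometryError, match="boundary edges"):
            label_slice(self._planes()[0], scar)


class TestEndToEndGeometry:
    def test_spheroid_wall_thickness_tracks_analytic(self):
        """Slice+rasterize a prolate spheroid shell; wall thickness at the
        equatorial plane must match the closed-form annulus thickness."""
        mesh = spheroid_shell()  # semi-axes (45,25,25)/(40,20,20) along x
        samples = slice_samples(mesh, min_pixels=50)
        # the mid slice passes near x=~... the slice closest to the center
        mid = min(
            (s for s in samples if s.valid),
            key=lambda s: abs(s.mask.normalized_position - 0.5),
        )
        x = (mid.mask.normalized_position - 0.5) * 90.0  # position along major axis
        r_epi = 25.0 * np.sqrt(max(1 - (x / 45.0) ** 2, 0.0))
        r_endo = 20.0 * np.sqrt(max(1 - (x / 40.0) ** 2, 0.0))
        analytic = r_epi - r_endo
        grid = mid.mask.grid
        row = grid[128, :]
        runs = np.flatnonzero(row)
        measured = row.sum() / 2.0  # two wall crossings along the row
        assert runs.size > 0
        assert abs(measured - analytic) <= 1.0

    def test_retained_count_bounded_by_n_slices(self, scarred_mesh):
        samples = slice_samples(scarred_mesh)
        assert len(samples) == 25
        assert sum(s.valid for s in samples) <= 25

    def test_points_inside_mesh_against_analytic_sphere(self):
        sph = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        rng = np.random.default_rng(1)
        pts = rng.uniform(-12, 12, size=(500, 3))
        inside = points_inside_mesh(sph.vertices, sph.faces, pts)
        r = np.linalg.norm(pts, axis=1)
        clear = np.abs(r - 10.0) > 0.25  # skip the facet-approximation shell
        assert np.array_equal(inside[clear], (r < 10.0)[clear])
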