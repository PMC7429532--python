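"""Geometry and forward-model physics of the spherical head model."""

import numpy as np
import pytest

import izbench
from izbench.headmodel import (
    DegenerateGeometryError,
    SensorKind,
    dipole_field,
    point_gain,
    single_point_gain,
)


class TestVolumeSourceSpace:
    def test_small_sphere_grid_enumerates_by_hand(self):
        # candidates {-5, 0, 5}^3 inside radius 6: origin plus one step
        # along each axis
        space = izbench.build_volume_source_space(6.0, 5.0, 0.0)
        assert space.n_points == 7
        norms = np.sort(np.linalg.norm(space.points, axis=1))
        assert np.allclose(norms, [0, 5, 5, 5, 5, 5, 5])

    def test_tiny_sphere_keeps_only_origin(self):
        space = izbench.build_volume_source_space(2.0, 5.0, 0.0)
        assert space.n_points == 1
        assert np.allclose(space.points, 0.0)

    def test_default_grid_geometry(self):
        space = izbench.build_volume_source_space(90.0, 5.0, 5.0)
        radii = np.linalg.norm(space.points, axis=1)
        assert radii.max() <= 85.0 + 1e-9
        # nearest-neighbour distance equals the spacing on a cubic grid
        from scipy.spatial import cKDTree

        d, _ = cKDTree(space.points).query(space.points, k=2)
        assert np.allclose(d[:, 1].min(), 5.0)
        assert np.allclose(np.median(d[:, 1]), 5.0)

    def test_empty_grid_raises(self):
        with pytest.raises(DegenerateGeometryError):
            izbench.build_volume_source_space(5.0, 5.0, 10.0)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_spacing_rejected(self, bad):
        with pytest.raises(ValueError):
            izbench.build_volume_source_space(90.0, bad, 5.0)


class TestCorticalLikeSourceSpace:
    def test_count_and_shell_band(self):
        space = izbench.build_cortical_like_source_space(
            8195, 90.0, (55.0, 80.0), seed=1
        )
        assert space.n_points == 8195
        radii = np.linalg.norm(space.points, axis=1)
        assert radii.min() >= 55.0 - 1e-9
        assert radii.max() <= 80.0 + 1e-9

    def test_seed_reproducibility_and_variation(self):
        a = izbench.build_cortical_like_source_space(200, 90.0, (55.0, 80.0), seed=3)
        b = izbench.build_cortical_like_source_space(200, 90.0, (55.0, 80.0), seed=3)
        c = izbench.build_cortical_like_source_space(200, 90.0, (55.0, 80.0), seed=4)
        assert np.array_equal(a.points, b.points)
        assert not np.array_equal(a.points, c.points)

    def test_shell_outside_head_raises(self):
        with pytest.raises(DegenerateGeometryError):
            izbench.build_cortical_like_source_space(100, 90.0, (55.0, 95.0), seed=0)


class TestSensorArray:
    def test_default_helmet_layout(self, sensors):
        assert sensors.n_channels == 204
        assert sensors.sensor_kind == SensorKind.planar_gradiometer
        radii = np.linalg.norm(sensors.positions, axis=1)
        assert np.allclose(radii, 110.0)
        # baselines orthogonal to the pickup orientation and to each other
        dot = np.einsum("mj,mj->m", sensors.orientations, sensors.baseline_dirs)
        assert np.abs(dot).max() < 1e-9
        pair_dot = np.einsum(
            "mj,mj->m", sensors.baseline_dirs[0::2], sensors.baseline_dirs[1::2]
        )
        assert np.abs(pair_dot).max() < 1e-9

    def test_sensor_inside_head_rejected(self):
        space = izbench.build_volume_source_space(90.0, 20.0, 5.0)
        inside = izbench.build_sensor_array(n_sites=20, radius=50.0)
        with pytest.raises(DegenerateGeometryError):
            izbench.sphere_leadfield(space, inside)


class TestSphereForward:
    def test_radial_component_matches_primary_dipole_field(self):
        """Independent closed-form oracle: outside any spherically symmetric
        conductor the radial field component is that of the primary current
        dipole alone, B.r_hat = k (q x (r - r0)).r_hat / |r - r0|^3."""
        rng = np.random.default_rng(0)
        r0 = np.array([30.0, 20.0, 40.0])
        q = np.array([120.0, -80.0, 60.0])
        pts = rng.standard_normal((40, 3))
        pts = 120.0 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        T = dipole_field(pts, r0[None, :])
        B = np.einsum("mjk,k->mj", T[:, 0], q)
        rhat = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        a = (pts - r0) * 1e-3
        primary = (
            1e-7
            * np.cross(np.tile(q * 1e-9, (40, 1)), a)
            / np.linalg.norm(a, axis=1, keepdims=True) ** 3
            * 1e15
        )
        assert np.allclose(
            np.einsum("mj,mj->m", B, rhat),
            np.einsum("mj,mj->m", primary, rhat),
            rtol=1e-12,
        )

    def test_radial_sources_are_silent(self, grid_head):
        space, leadfield, _ = grid_head
        blocks = leadfield.blocks()
        rng = np.random.default_rng(1)
        for j in rng.integers(0, space.n_points, size=25):
            p = space.points[j]
            if np.linalg.norm(p) < 1e-9:
                continue
            radial = p / np.linalg.norm(p)
            silent = np.linalg.norm(blocks[j] @ radial)
            total = np.linalg.norm(blocks[j])
            assert silent < 1e-10 * total

    def test_dipole_at_origin_is_silent(self, sensors):
        gain = single_point_gain(sensors, np.zeros(3))
        assert np.all(gain == 0.0)

    def test_linearity_in_the_moment(self, grid_head):
        _, leadfield, _ = grid_head
        q = np.array([10.0, -5.0, 2.0])
        y1 = leadfield.topography(100, q)
        y3 = leadfield.topography(100, 3.0 * q)
        assert np.allclose(y3, 3.0 * y1, rtol=1e-12)

    def test_rigid_rotation_covariance(self):
        """Rotating sources and sensors together leaves channels unchanged."""
        from izbench.headmodel import SensorArray

        rng = np.random.default_rng(5)
        a = rng.standard_normal((3, 3))
        Q, R = np.linalg.qr(a)
        Q *= np.sign(np.diag(R))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        sens = izbench.build_sensor_array(n_sites=30)
        loc = np.array([20.0, 35.0, 10.0])
        q = np.array([40.0, 10.0, -25.0])
        y = single_point_gain(sens, loc) @ q
        sens_rot = SensorArray(
            positions=sens.positions @ Q.T,
            orientations=sens.orientations @ Q.T,
            sensor_kind=sens.sensor_kind,
            baseline=sens.baseline,
            baseline_dirs=sens.baseline_dirs @ Q.T,
        )
        y_rot = single_point_gain(sens_rot, Q @ loc) @ (Q @ q)
        assert np.allclose(y, y_rot, atol=1e-9 * np.abs(y).max())

    def test_shallow_source_couples_stronger_than_deep(self, sensors):
        g = point_gain(sensors, np.array([[0.0, 0.0, 70.0], [0.0, 0.0, 30.0]]))
        assert np.linalg.norm(g[0]) > np.linalg.norm(g[1])

    def test_gradiometer_is_baseline_difference(self, sensors):
        loc = np.array([10.0, 25.0, 40.0])
        gain = single_point_gain(sensors, loc)
        half = 0.5 * sensors.baseline * sensors.baseline_dirs
        b_plus = np.einsum(
            "mj,mjk->mk",
            sensors.orientations,
            dipole_field(sensors.positions + half, loc[None, :])[:, 0],
        )
        b_minus = np.einsum(
            "mj,mjk->mk",
            sensors.orientations,
            dipole_field(sensors.positions - half, loc[None, :])[:, 0],
        )
        manual = (b_plus - b_minus) / (sensors.baseline / 10.0)
        assert np.allclose(gain, manual, rtol=1e-10)

    def test_leadfield_block_layout(self, grid_head):
        space, leadfield, _ = grid_head
        assert leadfield.matrix.shape == (204, 3 * space.n_points)
        j = 17
        block = leadfield.blocks()[j]
        assert np.array_equal(block, leadfield.matrix[:, 3 * j : 3 * j + 3])


class TestFileRoundTrips:
    def test_source_space_file_round_trip(self, tmp_path):
        import izbench.io as iz_io

        space = izbench.build_volume_source_space(60.0, 15.0, 5.0)
        labels = izbench.assign_lobes(space)
        path = tmp_path / "space.csv"
        iz_io.save_source_space(space, labels, path)
        back, back_labels = iz_io.load_source_space(
            path, kind=space.kind, spacing=space.spacing, head_radius=space.head_radius
        )
        assert np.allclose(back.points, space.points)
        assert back_labels.labels == labels.labels

    def test_leadfield_file_round_trip(self, tmp_path, sensors):
        import izbench.io as iz_io

        space = izbench.build_volume_source_space(60.0, 25.0, 5.0)
        leadfield = izbench.sphere_leadfield(space, sensors)
        path = tmp_path / "leadfield.csv"
        iz_io.save_leadfield(leadfield, path)
        back = iz_io.load_leadfield(path, space)
        assert back.channel_names == leadfield.channel_names
        assert np.allclose(back.matrix, leadfield.matrix, rtol=1e-12)
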