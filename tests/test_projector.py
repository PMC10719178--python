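"""System-model (projector/backprojector) contracts."""

import numpy as np
import pytest

from ybremdose.projector import (CDRModel, ProjectionGeometry, ProjectionSet,
                                 add_poisson_noise, backproject, load_projections,
                                 project, project_attenuation, save_projections)
from ybremdose.volumes import VoxelGrid, VoxelVolume


def _rand_vol(grid, rng, quantity="activity_MBq", scale=1.0):
    return VoxelVolume(grid, rng.random(grid.shape) * scale, quantity)


class TestAdjointness:
    def test_inner_product_identity_20_pairs(self, tiny_grid, tiny_geom, tiny_cdr):
        rng = np.random.default_rng(1)
        mu = _rand_vol(tiny_grid, rng, "attenuation_per_cm", 0.03)
        for _ in range(20):
            x = _rand_vol(tiny_grid, rng)
            p = ProjectionSet(tiny_geom, rng.random(
                (tiny_geom.n_views, tiny_geom.n_bins_u, tiny_geom.n_bins_v)), "mean_primary")
            ax = project(x, mu, tiny_geom, tiny_cdr, efficiency=1.3)
            atp = backproject(p, mu, tiny_grid, tiny_geom, tiny_cdr, efficiency=1.3)
            lhs = float((ax.values * p.values).sum())
            rhs = float((x.values * atp.values).sum())
            assert abs(lhs - rhs) / abs(lhs) <= 1e-6

    def test_zero_projections_backproject_to_zero(self, tiny_grid, tiny_geom):
        p = ProjectionSet(tiny_geom, np.zeros(
            (tiny_geom.n_views, tiny_geom.n_bins_u, tiny_geom.n_bins_v)), "mean_primary")
        b = backproject(p, None, tiny_grid, tiny_geom, CDRModel.off())
        assert b.values.max() == 0.0

    def test_sensitivity_matches_direct_summation(self):
        # with mu=0 and CDR off the adjoint of "sum along rays" applied to
        # all-ones projections counts, per voxel, its splat weight per view
        grid = VoxelGrid((8, 8, 4), (4.8, 4.8, 4.8))
        geom = ProjectionGeometry(n_views=4, n_bins_u=8, n_bins_v=4, radius_mm=40)
        ones = ProjectionSet(geom, np.ones((4, 8, 4)), "mean_primary")
        sens = backproject(ones, None, grid, geom, CDRModel.off())
        # oracle: project unit impulses and sum each one's projections
        oracle = np.zeros(grid.shape)
        for i in range(8):
            for j in range(8):
                e = np.zeros(grid.shape)
                e[i, j, 0] = 1.0
                oracle[i, j, 0] = project(
                    VoxelVolume(grid, e, "activity_MBq"), None, geom,
                    CDRModel.off()).values.sum()
        assert np.allclose(sens.values[:, :, 0], oracle[:, :, 0], atol=1e-10)
        interior = sens.values[2:6, 2:6, 1:3]
        assert interior.min() > 0


class TestProjection:
    def test_point_source_at_isocenter(self):
        # odd grid so the centre voxel sits exactly on the rotation axis
        grid = VoxelGrid((17, 17, 5), (4.8, 4.8, 4.8))
        geom = ProjectionGeometry(n_views=8, n_bins_u=17, n_bins_v=5, radius_mm=60)
        x = np.zeros(grid.shape)
        x[8, 8, 2] = 1.0
        p = project(VoxelVolume(grid, x, "activity_MBq"), None, geom,
                    CDRModel.off(), efficiency=2.5)
        for v in range(8):
            nz = p.values[v][p.values[v] > 1e-12]
            assert nz.size == 1
            assert nz[0] == pytest.approx(2.5, rel=1e-12)

    def test_attenuation_factor_analytic(self, tiny_grid, tiny_geom):
        # point source with a uniform-mu slab of 7.5 voxel planes (half its
        # own plane plus 7 full planes) between it and the view-0 detector
        x = np.zeros(tiny_grid.shape)
        x[8, 8, 4] = 1.0
        mu_val = 0.05
        mu = np.zeros(tiny_grid.shape)
        mu[8, 8:16, 4] = mu_val
        p = project(VoxelVolume(tiny_grid, x, "activity_MBq"),
                    VoxelVolume(tiny_grid, mu, "attenuation_per_cm"),
                    tiny_geom, CDRModel.off())
        path_cm = 7.5 * 0.48
        assert p.values[0].sum() == pytest.approx(np.exp(-mu_val * path_cm), rel=1e-9)

    def test_linearity(self, tiny_grid, tiny_geom, tiny_cdr):
        rng = np.random.default_rng(5)
        mu = _rand_vol(tiny_grid, rng, "attenuation_per_cm", 0.02)
        x1, x2 = _rand_vol(tiny_grid, rng), _rand_vol(tiny_grid, rng)
        s = VoxelVolume(tiny_grid, x1.values + x2.values, "activity_MBq")
        p12 = project(s, mu, tiny_geom, tiny_cdr)
        p1 = project(x1, mu, tiny_geom, tiny_cdr)
        p2 = project(x2, mu, tiny_geom, tiny_cdr)
        assert np.allclose(p12.values, p1.values + p2.values, rtol=1e-10)

    def test_count_conservation_interior_object(self, tiny_grid, tiny_geom):
        rng = np.random.default_rng(2)
        x = np.zeros(tiny_grid.shape)
        x[5:11, 5:11, 2:6] = rng.random((6, 6, 4))
        p = project(VoxelVolume(tiny_grid, x, "activity_MBq"), None, tiny_geom,
                    CDRModel.off(), efficiency=1.0)
        total = x.sum()
        for v in range(tiny_geom.n_views):
            assert p.values[v].sum() == pytest.approx(total, rel=1e-6)

    def test_cdr_blur_conserves_interior_counts(self, tiny_grid, tiny_geom):
        x = np.zeros(tiny_grid.shape)
        x[7:9, 7:9, 3:5] = 1.0
        p = project(VoxelVolume(tiny_grid, x, "activity_MBq"), None, tiny_geom,
                    CDRModel(c0_mm=3.0, c1=0.02))
        for v in range(tiny_geom.n_views):
            assert p.values[v].sum() == pytest.approx(x.sum(), rel=1e-3)

    def test_pitch_mismatch_rejected(self, tiny_geom):
        bad = VoxelGrid((16, 16, 8), (2.0, 2.0, 2.0))
        x = VoxelVolume(bad, np.ones(bad.shape), "activity_MBq")
        with pytest.raises(ValueError, match="resample"):
            project(x, None, tiny_geom, CDRModel.off())


class TestAttenuationProjection:
    def test_zero_mu(self, tiny_grid, tiny_geom):
        mu = VoxelVolume(tiny_grid, np.zeros(tiny_grid.shape), "attenuation_per_cm")
        p = project_attenuation(mu, tiny_geom)
        assert p.values.max() == 0.0
        assert p.kind == "attenuation_line_integral"

    def test_uniform_slab_line_integral(self, tiny_grid, tiny_geom):
        mu = np.zeros(tiny_grid.shape)
        mu[8, 4:12, 4] = 0.1  # 8 planes of 4.8 mm
        p = project_attenuation(VoxelVolume(tiny_grid, mu, "attenuation_per_cm"), tiny_geom)
        assert p.values[0, 8, 4] == pytest.approx(0.1 * 8 * 0.48, rel=1e-9)

    def test_cyclic_consistency_quarter_turns(self):
        # rotating the phantom by one 90-degree view increment equals
        # shifting the view index by one
        grid = VoxelGrid((17, 17, 5), (4.8, 4.8, 4.8))
        geom = ProjectionGeometry(n_views=4, n_bins_u=17, n_bins_v=5, radius_mm=60)
        rng = np.random.default_rng(3)
        mu = np.zeros(grid.shape)
        mu[4:13, 4:13, 1:4] = rng.random((9, 9, 3)) * 0.05
        p0 = project_attenuation(VoxelVolume(grid, mu, "attenuation_per_cm"), geom)
        mu_rot = np.rot90(mu, k=1, axes=(0, 1)).copy()  # 90 deg CCW in-plane
        p1 = project_attenuation(VoxelVolume(grid, mu_rot, "attenuation_per_cm"), geom)
        for v in range(4):
            a = p0.values[(v + 1) % 4]
            b = p1.values[v]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, b[::-1], atol=1e-8)


class TestPoissonNoise:
    def test_expected_total_1e7(self, tiny_grid, tiny_geom, smooth_phantom):
        p = project(smooth_phantom, None, tiny_geom, CDRModel.off())
        y, scale = add_poisson_noise(p, 1e7, seed=11)
        assert scale == pytest.approx(1e7 / p.total())
        assert abs(y.total() - 1e7) <= 4 * np.sqrt(1e7)
        assert np.allclose(y.values, np.round(y.values))

    def test_zero_mean_zero_target(self, tiny_geom):
        z = ProjectionSet(tiny_geom, np.zeros(
            (tiny_geom.n_views, tiny_geom.n_bins_u, tiny_geom.n_bins_v)), "mean_scatter")
        y, scale = add_poisson_noise(z, 0.0, seed=0)
        assert y.total() == 0.0

    def test_zero_mean_positive_target_rejected(self, tiny_geom):
        z = ProjectionSet(tiny_geom, np.zeros(
            (tiny_geom.n_views, tiny_geom.n_bins_u, tiny_geom.n_bins_v)), "mean_scatter")
        with pytest.raises(ValueError):
            add_poisson_noise(z, 100.0, seed=0)

    def test_seeded_determinism(self, tiny_geom, smooth_phantom, tiny_grid):
        p = project(smooth_phantom, None, tiny_geom, CDRModel.off())
        y1, _ = add_poisson_noise(p, 1e5, seed=4)
        y2, _ = add_poisson_noise(p, 1e5, seed=4)
        assert np.array_equal(y1.values, y2.values)


def test_hdf5_round_trip(tmp_path, tiny_geom):
    rng = np.random.default_rng(0)
    p = ProjectionSet(tiny_geom, rng.random(
        (tiny_geom.n_views, tiny_geom.n_bins_u, tiny_geom.n_bins_v)), "mean_scatter")
    f = tmp_path / "p.h5"
    save_projections(p, str(f), extra={"seed": 3})
    q = load_projections(str(f))
    assert np.allclose(q.values, p.values)
    assert q.kind == p.kind
    assert q.geometry == p.geometry
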