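"""Forward projection: Beer-Lambert line integrals, binomial statistics,
mask projection, geometry."""

import dataclasses

import numpy as np
import pytest

from shuntscope import (AttenuationTable, MaterialVolume, ProjectionGeometry,
                        make_scene, path_integrals, project_mask,
                        render_frame, sample_counts, transmission)
from shuntscope.materials import CAVITY, SHELL, TANTALUM_BALL, BACKGROUND
from shuntscope.projector import FrameSimulator, _RaySampler, make_water_scene
from shuntscope.scene import Scene, scene_mu_volume


def _block_volume(n=40, vox=0.5, label=CAVITY):
    labels = np.full((n, n, n), label, dtype=np.uint8)
    origin = np.array([-(n - 1) / 2 * vox] * 3)
    return MaterialVolume(labels=labels, voxel_size=vox, origin=origin)


class TestPathIntegrals:
    def test_empty_scene_gives_zero(self, attenuation):
        vol = _block_volume(16, 0.5, label=BACKGROUND)
        scene = make_water_scene(vol)
        tau = path_integrals(scene, attenuation, ProjectionGeometry())
        assert np.all(tau == 0)

    def test_water_slab_matches_analytic_formula(self, attenuation):
        """2 cm of water: tau = 0.206 * 2 = 0.412 at central pixels."""
        scene = make_water_scene(_block_volume(40, 0.5))
        geom = ProjectionGeometry()
        tau = path_integrals(scene, attenuation, geom)
        center = tau[geom.rows // 2, geom.cols // 2]
        # trilinear edge ramps shave ~half a voxel per face
        assert center == pytest.approx(0.412, rel=0.03)

    def test_superposition_of_material_groups(self, fixture_volume,
                                              attenuation):
        """Projecting shell-only and interior-only scenes separately and
        summing equals projecting the combined scene."""
        geom = ProjectionGeometry(pitch_mm=2.0, rows=64, cols=64,
                                  pose_angle_deg=25.0)
        full = make_scene(fixture_volume, 2.0, None, pose_angle=25.0)

        shell_labels = np.where(fixture_volume.labels == SHELL, SHELL,
                                BACKGROUND).astype(np.uint8)
        rest_labels = np.where(fixture_volume.labels == SHELL, BACKGROUND,
                               fixture_volume.labels).astype(np.uint8)
        shell_vol = dataclasses.replace(fixture_volume, labels=shell_labels)
        rest_vol = dataclasses.replace(fixture_volume, labels=rest_labels)
        tau_shell = path_integrals(make_scene(shell_vol, 2.0, None,
                                              pose_angle=25.0),
                                   attenuation, geom)
        tau_rest = path_integrals(make_scene(rest_vol, 2.0, None,
                                             pose_angle=25.0),
                                  attenuation, geom)
        tau_full = path_integrals(full, attenuation, geom)
        assert np.allclose(tau_shell + tau_rest, tau_full, atol=1e-4)

    def test_rejects_coarse_sampling_step(self, fixture_volume, attenuation):
        scene = make_water_scene(fixture_volume)
        with pytest.raises(ValueError, match="step"):
            path_integrals(scene, attenuation, ProjectionGeometry(),
                           step_mm=fixture_volume.voxel_size * 2)

    def test_detector_refinement_leaves_tau_unchanged(self, attenuation):
        """Doubling the matrix while halving the pitch probes the same
        beam; on a smooth object the interpolated coarse map matches."""
        scene = make_water_scene(_block_volume(30, 0.5))
        coarse = ProjectionGeometry(pitch_mm=2.0, rows=32, cols=32)
        fine = ProjectionGeometry(pitch_mm=1.0, rows=64, cols=64)
        t_c = path_integrals(scene, attenuation, coarse)
        t_f = path_integrals(scene, attenuation, fine)
        # average fine 2x2 blocks -> coarse pixel centers
        t_f_avg = t_f.reshape(32, 2, 32, 2).mean(axis=(1, 3))
        inner = np.s_[10:22, 10:22]
        assert np.allclose(t_f_avg[inner], t_c[inner], atol=0.02)


class TestTransmission:
    @pytest.mark.parametrize("tau,expected", [
        (0.0, 1.0),
        (np.log(2.0), 0.5),
        (0.412, 0.6623242760521223),
    ])
    def test_closed_form_values(self, tau, expected):
        assert transmission(np.array([tau]))[0] == pytest.approx(expected)

    def test_rejects_negative_depth(self):
        with pytest.raises(ValueError):
            transmission(np.array([-0.1]))


class TestSampleCounts:
    def test_degenerate_probabilities(self):
        p1 = np.ones((8, 8))
        assert np.all(sample_counts(p1, 400, seed=0) == 400)
        assert np.all(sample_counts(np.zeros((8, 8)), 400, seed=0) == 0)

    def test_counts_within_binomial_support(self):
        c = sample_counts(np.full((32, 32), 0.3), 100, seed=1)
        assert c.min() >= 0 and c.max() <= 100

    def test_binomial_moments(self):
        """1e5 draws at p = 0.5, N0 = 400: mean ~ 200, variance ~ 100."""
        n = 100_000
        draws = sample_counts(np.full(n, 0.5), 400, seed=42).astype(float)
        sigma = np.sqrt(400 * 0.25)
        assert abs(draws.mean() - 200.0) < 3 * sigma / np.sqrt(n)
        assert abs(draws.var() - 100.0) / 100.0 < 0.05

    def test_reproducible_under_seed(self):
        p = np.random.default_rng(3).random((16, 16))
        assert np.array_equal(sample_counts(p, 400, seed=5),
                              sample_counts(p, 400, seed=5))

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            sample_counts(np.array([1.5]), 400)
        with pytest.raises(ValueError):
            sample_counts(np.array([0.5]), 0)


class TestProjectMask:
    def test_clean_scene_gives_empty_mask(self, fixture_volume):
        scene = make_scene(fixture_volume, 2.0, None, pose_angle=0.0)
        assert not project_mask(scene, ProjectionGeometry()).mask.any()

    def test_single_voxel_obstruction_projects_inside_cavity_footprint(
            self, fixture_volume, attenuation):
        vox3 = fixture_volume.voxel_size ** 3
        scene = make_scene(fixture_volume, 2.0, vox3, pose_angle=70.0, seed=9)
        geom = ProjectionGeometry(pitch_mm=2.0, rows=64, cols=64)
        mask = project_mask(scene, geom).mask
        assert mask.sum() >= 1
        # every mask pixel must lie within the cavity's projected footprint
        sampler = _RaySampler(fixture_volume,
                              dataclasses.replace(geom, pose_angle_deg=70.0))
        from shuntscope import cavity_mask
        l_cav = sampler.integrate(cavity_mask(fixture_volume).astype(np.float32))
        assert np.all(l_cav[mask] > 0)

    def test_matches_exhaustive_ray_voxel_oracle(self, fixture_volume):
        """Brute force: test every (pixel, voxel) ray-box intersection."""
        scene = make_scene(fixture_volume, 2.0, 0.08, pose_angle=33.0, seed=2)
        geom = ProjectionGeometry(pitch_mm=4.0, rows=32, cols=32)
        mask = project_mask(scene, geom).mask

        vol = fixture_volume
        th = np.deg2rad(33.0)
        c, s = np.cos(th), np.sin(th)
        rot = np.array([[1, 0, 0], [0, c, s], [0, -s, c]])
        center = vol.origin + vol.voxel_size * (np.array(vol.shape) - 1) / 2
        sod, sdd = geom.sod_cm * 10, geom.sdd_cm * 10
        origin = rot @ np.array([0.0, 0.0, -sod]) + center
        vox = vol.voxel_size
        boxes = [(vol.origin + idx * vox - vox / 2,
                  vol.origin + idx * vox + vox / 2)
                 for idx in np.argwhere(scene.obstruction)]

        oracle = np.zeros_like(mask)
        for i in range(geom.rows):
            for j in range(geom.cols):
                u = (i - (geom.rows - 1) / 2) * geom.pitch_mm
                v = (j - (geom.cols - 1) / 2) * geom.pitch_mm
                d = rot @ np.array([u, v, sdd])
                for lo, hi in boxes:
                    tmin, tmax = -np.inf, np.inf
                    ok = True
                    for ax in range(3):
                        if d[ax] == 0:
                            if not lo[ax] <= origin[ax] <= hi[ax]:
                                ok = False
                                break
                            continue
                        ta = (lo[ax] - origin[ax]) / d[ax]
                        tb = (hi[ax] - origin[ax]) / d[ax]
                        tmin = max(tmin, min(ta, tb))
                        tmax = min(tmax, max(ta, tb))
                    if ok and tmax > tmin:
                        oracle[i, j] = True
                        break
        assert np.array_equal(mask, oracle)


class TestRenderFrame:
    def test_geometric_magnification(self):
        """SOD 5.5 cm / SDD 35 cm: a 1 mm shift spans ~6.36 mm on the
        detector, per similar triangles."""
        geom = ProjectionGeometry()
        assert geom.magnification == pytest.approx(35.0 / 5.5)

        # project a small opaque sphere at two lateral positions 1 mm apart
        n, vox = 41, 0.1
        labels = np.zeros((n, n, n), dtype=np.uint8)
        origin = np.array([-(n - 1) / 2 * vox] * 2 + [-(n - 1) / 2 * vox])
        grid = origin[0] + vox * np.arange(n)
        xx, yy, zz = np.meshgrid(grid, grid, grid, indexing="ij")
        centroids = []
        fine = ProjectionGeometry(pitch_mm=0.2, rows=128, cols=128)
        att = AttenuationTable()
        for y0 in (0.0, 1.0):
            lab = np.where((xx - y0) ** 2 + yy ** 2 + zz ** 2 <= 1.0 ** 2,
                           TANTALUM_BALL, 0).astype(np.uint8)
            vol = MaterialVolume(labels=lab, voxel_size=vox, origin=origin)
            tau = path_integrals(make_water_scene(vol), att, fine)
            w = tau.sum(axis=1)
            centroids.append((np.arange(128) * w).sum() / w.sum())
        shift_mm = (centroids[1] - centroids[0]) * fine.pitch_mm
        assert shift_mm == pytest.approx(35.0 / 5.5, rel=0.02)

    def test_deterministic_under_seed(self, fixture_volume, attenuation,
                                      small_geometry):
        scene = make_scene(fixture_volume, 2.0, 0.3, seed=11)
        a = render_frame(scene, attenuation, small_geometry, 400, seed=4)
        b = render_frame(scene, attenuation, small_geometry, 400, seed=4)
        assert np.array_equal(a[0].counts, b[0].counts)
        assert np.array_equal(a[1].mask, b[1].mask)
        assert a[0].pose_angle_deg == b[0].pose_angle_deg

    def test_contrast_reduces_cavity_counts(self, fixture_volume, attenuation,
                                            small_geometry):
        """Raising concentration 0 -> 2 mmol/ml strictly lowers expected
        counts behind the cavity (monotonicity of exp(-tau) in mu)."""
        taus = {}
        for c in (0.0, 2.0):
            scene = make_scene(fixture_volume, c, None, pose_angle=50.0)
            taus[c] = path_integrals(scene, attenuation, small_geometry)
        from shuntscope import cavity_mask
        sampler = _RaySampler(fixture_volume,
                              dataclasses.replace(small_geometry,
                                                  pose_angle_deg=50.0))
        footprint = sampler.integrate(
            cavity_mask(fixture_volume).astype(np.float32)) > 0
        mean0 = (400 * np.exp(-taus[0.0]))[footprint].mean()
        mean2 = (400 * np.exp(-taus[2.0]))[footprint].mean()
        assert mean2 < mean0
        assert np.all(taus[2.0][footprint] > taus[0.0][footprint])


class TestFrameSimulator:
    def test_fast_path_matches_direct_projection(self, fixture_volume,
                                                 attenuation, small_geometry):
        sim = FrameSimulator(fixture_volume, attenuation, small_geometry,
                             n_angles=24)
        scene = make_scene(fixture_volume, 2.0, 0.5,
                           pose_angle=sim.angle_deg(5), seed=6)
        tau_fast = sim.tau_frame(2.0, 5, scene.obstruction)
        tau_direct = path_integrals(scene, attenuation, small_geometry)
        assert np.allclose(tau_fast, tau_direct, atol=2e-4)

    def test_obstruction_raises_counts_in_mask(self, simulator,
                                               fixture_volume):
        """Water in place of contrast transmits more: expected counts in
        mask pixels rise relative to the unobstructed twin."""
        scene = make_scene(fixture_volume, 2.0, 0.7,
                           pose_angle=simulator.angle_deg(3), seed=8)
        geom = dataclasses.replace(simulator.geometry,
                                   pose_angle_deg=simulator.angle_deg(3))
        tau_clean = simulator.tau_frame(2.0, 3, None)
        tau_obs = simulator.tau_frame(2.0, 3, scene.obstruction)
        mask = project_mask(scene, geom).mask
        assert np.all(tau_obs <= tau_clean + 1e-6)
        assert (np.exp(-tau_obs) - np.exp(-tau_clean))[mask].mean() > 0

    def test_render_deterministic(self, simulator):
        a = simulator.render(np.random.default_rng(5), 400, 2.0, 0.4)
        b = simulator.render(np.random.default_rng(5), 400, 2.0, 0.4)
        assert np.array_equal(a[0].counts, b[0].counts)
        assert np.array_equal(a[1].mask, b[1].mask)


def test_geometry_validation():
    with pytest.raises(ValueError):
        ProjectionGeometry(sod_cm=40.0, sdd_cm=35.0)
    with pytest.raises(ValueError):
        ProjectionGeometry(pitch_mm=-1.0)
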