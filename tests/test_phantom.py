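"""Phantom generator: deformation fields, sphere rendering, ground truth."""

import numpy as np
import pandas as pd
import pytest

import shrinkvec as sv
from shrinkvec.phantom import (ConfigurationError, DeformationModel, Layer,
                               PhantomError, PhantomSpec,
                               evaluate_deformation, generate_phantom,
                               inverse_deformation, rasterize_sphere)
from shrinkvec.volume import Volume


def _model(kind, **kw):
    return DeformationModel(kind=kind, **kw)


class TestEvaluateDeformation:
    def test_none_is_zero_everywhere(self, rng):
        pts = rng.uniform(-1000, 1000, size=(50, 3))
        np.testing.assert_array_equal(
            evaluate_deformation(pts, _model("none")), np.zeros_like(pts))

    def test_uniform_contraction_is_linear(self):
        m = _model("uniform_contraction", center=(0.0, 0.0, 0.0),
                   contraction_fraction=0.01)
        u = evaluate_deformation(np.array([100.0, 0.0, 0.0]), m)
        np.testing.assert_allclose(u, [-1.0, 0.0, 0.0], atol=1e-12)

    def test_axial_drift_is_constant_z(self, rng):
        m = _model("axial_drift", axial_shift=7.5)
        pts = rng.uniform(-500, 500, size=(20, 3))
        u = evaluate_deformation(pts, m)
        np.testing.assert_array_equal(u[:, :2], 0.0)
        np.testing.assert_array_equal(u[:, 2], 7.5)

    def test_swirl_preserves_radius(self, rng):
        m = _model("swirl", center=(100.0, 200.0, 0.0), swirl_deg_per_mm=30.0)
        pts = rng.uniform(-800, 800, size=(30, 3)) + [100, 200, 0]
        moved = pts + evaluate_deformation(pts, m)
        r0 = np.hypot(pts[:, 0] - 100, pts[:, 1] - 200)
        r1 = np.hypot(moved[:, 0] - 100, moved[:, 1] - 200)
        np.testing.assert_allclose(r1, r0, rtol=1e-9)
        np.testing.assert_array_equal(moved[:, 2], pts[:, 2])

    def test_composite_sum_equals_sum_of_parts(self, rng):
        parts = (
            _model("uniform_contraction", center=(10.0, 20.0, 30.0),
                   contraction_fraction=0.02),
            _model("axial_drift", axial_shift=-3.0),
        )
        m = _model("composite_sum", parts=parts)
        pts = rng.uniform(-400, 400, size=(25, 3))
        expected = sum(evaluate_deformation(pts, p) for p in parts)
        np.testing.assert_allclose(evaluate_deformation(pts, m), expected,
                                   atol=1e-12)

    def test_unknown_kind_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            DeformationModel(kind="explode")

    @pytest.mark.parametrize("kind,kw", [
        ("uniform_contraction", dict(contraction_fraction=0.03,
                                     center=(50.0, -20.0, 10.0))),
        ("axial_drift", dict(axial_shift=12.0)),
        ("swirl", dict(swirl_deg_per_mm=25.0, center=(0.0, 0.0, 0.0))),
        ("composite_sum", dict(parts=(
            DeformationModel(kind="uniform_contraction",
                             contraction_fraction=0.01),
            DeformationModel(kind="axial_drift", axial_shift=4.0)))),
    ])
    def test_inverse_deformation_round_trip(self, kind, kw, rng):
        m = _model(kind, **kw)
        pts = rng.uniform(-300, 300, size=(40, 3))
        moved = pts + evaluate_deformation(pts, m)
        np.testing.assert_allclose(inverse_deformation(moved, m), pts,
                                   atol=1e-6)


class TestRasterizeSphere:
    def _vol(self, n=32, value=1000.0):
        return Volume(np.full((n, n, n), value, dtype=np.float32),
                      np.full(3, 16.0))

    def test_coverage_matches_analytic_sphere_volume(self):
        vol = self._vol()
        rasterize_sphere(vol, (16 * 16, 16 * 16, 16 * 16), radius=5 * 16.0,
                         attenuation=0.0, supersampling=3)
        # blended fraction f per voxel: value = 1000 (1 - f)
        total = np.sum(1.0 - vol.data / 1000.0)
        assert total == pytest.approx(4.0 / 3.0 * np.pi * 5 ** 3, rel=0.02)

    def test_subvoxel_sphere_touches_single_voxel(self):
        vol = self._vol(n=8)
        center = vol.voxel_to_world(np.array([4, 4, 4]))
        rasterize_sphere(vol, center, radius=0.1 * 16.0, attenuation=0.0,
                         supersampling=5)
        changed = np.argwhere(vol.data != 1000.0)
        assert changed.tolist() == [[4, 4, 4]]
        frac = 1.0 - vol.data[4, 4, 4] / 1000.0
        assert 0.0 < frac < 1.0

    def test_disjoint_spheres_commute(self):
        a = self._vol()
        b = self._vol()
        c1, c2 = (100.0, 100.0, 100.0), (400.0, 380.0, 360.0)
        rasterize_sphere(a, c1, 40.0, 200.0)
        rasterize_sphere(a, c2, 30.0, 200.0)
        rasterize_sphere(b, c2, 30.0, 200.0)
        rasterize_sphere(b, c1, 40.0, 200.0)
        np.testing.assert_array_equal(a.data, b.data)

    def test_fully_outside_sphere_warns_and_is_noop(self):
        vol = self._vol(n=8)
        with pytest.warns(UserWarning, match="outside"):
            rasterize_sphere(vol, (-5000.0, 0.0, 0.0), 16.0, 0.0)
        assert np.all(vol.data == 1000.0)

    @pytest.mark.parametrize("radius_vox", [1.25, 1.6, 2.2])
    def test_integrated_radiolucency_scales_with_volume(self, radius_vox):
        vol = self._vol()
        rasterize_sphere(vol, (16 * 16 + 5.3, 16 * 16 - 2.1, 16 * 16 + 7.7),
                         radius=radius_vox * 16.0, attenuation=400.0,
                         supersampling=3)
        integrated = np.sum(1000.0 - vol.data) / (1000.0 - 400.0)
        assert integrated == pytest.approx(
            4.0 / 3.0 * np.pi * radius_vox ** 3, rel=0.05)


class TestPhantomSpecValidation:
    def test_cavity_must_fit_with_margin(self):
        with pytest.raises(ConfigurationError, match="clearance"):
            PhantomSpec(grid_shape=(64, 64, 64), cavity_diameter=1600.0)

    def test_bead_diameters_must_fit_cavity(self):
        with pytest.raises(ConfigurationError, match="bead_diameter_range"):
            sv.small_spec(bead_diameter_range=(40.0, 700.0))

    def test_overlapping_layers_rejected(self):
        with pytest.raises(ConfigurationError, match="overlap"):
            sv.small_spec(layers=(
                Layer("a", 0.0, 400.0, 1000.0),
                Layer("b", 300.0, 640.0, 1400.0)))

    def test_negative_attenuation_rejected(self):
        with pytest.raises(ConfigurationError, match="attenuation"):
            sv.small_spec(bead_attenuation=-1.0)


class TestGeneratePhantom:
    def test_equal_seeds_are_bit_identical(self):
        spec = sv.small_spec(seed=7, noise_sd=60.0)
        d = DeformationModel(kind="uniform_contraction",
                             center=spec.floor_center,
                             contraction_fraction=0.01)
        pose = sv.RigidTransform(angles_zyx=(1.0, 0.0, 0.0),
                                 translation=(8.0, -4.0, 2.0),
                                 center=(576.0, 576.0, 576.0))
        a = generate_phantom(spec, d, pose)
        b = generate_phantom(spec, d, pose)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[1].data, b[1].data)
        pd.testing.assert_frame_equal(a[2].table, b[2].table)

    def test_static_noise_free_pair_is_self_consistent(self,
                                                       small_static_pair):
        _, pre, post, _ = small_static_pair
        np.testing.assert_array_equal(pre.data, post.data)

    def test_truth_has_unique_ids_and_respects_spacing(self,
                                                       small_static_pair):
        spec, _, _, truth = small_static_pair
        t = truth.table
        assert t["id"].is_unique and len(t) == spec.bead_count
        centers = t[["x_pre", "y_pre", "z_pre"]].to_numpy()
        radii = t["radius_um"].to_numpy()
        d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        min_allowed = radii[:, None] + radii[None, :]
        np.fill_diagonal(d, np.inf)
        np.fill_diagonal(min_allowed, 0.0)
        assert np.all(d >= min_allowed)

    def test_truth_displacements_equal_field_at_pre_centers(
            self, small_contraction_pair):
        _, deformation, _, _, truth = small_contraction_pair
        t = truth.table
        u = evaluate_deformation(
            t[["x_pre", "y_pre", "z_pre"]].to_numpy(), deformation)
        np.testing.assert_allclose(t[["dx", "dy", "dz"]].to_numpy(), u,
                                   atol=1e-9)

    def test_contraction_mean_displacement_magnitude(
            self, small_contraction_pair):
        """Mean |u| equals s × mean distance to the contraction centre."""
        spec, deformation, _, _, truth = small_contraction_pair
        t = truth.table
        dist = np.linalg.norm(
            t[["x_pre", "y_pre", "z_pre"]].to_numpy()
            - np.asarray(spec.floor_center), axis=1)
        mags = np.linalg.norm(t[["dx", "dy", "dz"]].to_numpy(), axis=1)
        assert mags.mean() == pytest.approx(0.01 * dist.mean(), rel=1e-6)

    def test_noise_draws_differ_between_scans(self):
        spec = sv.small_spec(seed=9, noise_sd=60.0)
        pre, post, _ = generate_phantom(spec, None, None)
        assert not np.array_equal(pre.data, post.data)

    def test_placement_budget_exhaustion_reports_achieved_count(self):
        spec = sv.small_spec(bead_count=5000)
        with pytest.raises(PhantomError, match=r"after \d+ of 5000"):
            generate_phantom(spec, None, None)
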