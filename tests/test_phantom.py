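"""Phantom synthesis: anatomy, TPS, deformation components, EOT, dose."""

import numpy as np
import pytest

import dirqa as dq
from dirqa.grid import ImageGrid, ScalarVolume, VectorField, jacobian_determinant, warp_volume
from dirqa.phantom import (
    AnatomyConfig,
    DeformationModel,
    DosePlanSpec,
    build_anatomy,
    build_ground_truth_mapping,
    synthesize_dose,
    synthesize_eot,
    tps_field,
)

SMALL = AnatomyConfig(shape=(48, 48, 48), spacing=(3.0, 3.0, 3.0))


@pytest.fixture(scope="module")
def anatomy():
    return build_anatomy(SMALL, seed=3)


def tps_oracle(control_points, displacements, query):
    """Independent dense solve of the TPS system: kernel |r| + affine term."""
    p = np.asarray(control_points, dtype=float)
    d = np.asarray(displacements, dtype=float)
    n = len(p)
    K = np.linalg.norm(p[:, None, :] - p[None, :, :], axis=-1)
    P = np.c_[np.ones(n), p]
    A = np.zeros((n + 4, n + 4))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = d
    sol = np.linalg.solve(A, rhs)
    w, c = sol[:n], sol[n:]
    q = np.asarray(query, dtype=float)
    kq = np.linalg.norm(q[:, None, :] - p[None, :, :], axis=-1)
    return kq @ w + np.c_[np.ones(len(q)), q] @ c


class TestAnatomy:
    def test_deterministic_given_seed(self):
        v1, m1 = build_anatomy(SMALL, seed=5)
        v2, m2 = build_anatomy(SMALL, seed=5)
        assert np.array_equal(v1.values, v2.values)
        for name in m1:
            assert np.array_equal(m1[name].membership, m2[name].membership)

    def test_six_rois_nonempty_and_contained(self, anatomy):
        _, masks = anatomy
        assert set(masks) == set(dq.ROI_NAMES)
        ext = masks["external"].membership
        for name, mask in masks.items():
            assert mask.n_voxels > 0
            assert (mask.membership <= ext).all()

    def test_organ_masks_pairwise_disjoint(self, anatomy):
        _, masks = anatomy
        organs = [n for n in masks if n != "external"]
        for i, a in enumerate(organs):
            for b in organs[i + 1:]:
                assert not (masks[a].membership & masks[b].membership).any(), (a, b)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            build_anatomy(AnatomyConfig(shape=(16, 16, 16), spacing=(2, 2, 2)))


class TestTPS:
    def test_interpolates_control_points(self, rng):
        pts = rng.uniform(10, 120, size=(8, 3))
        disp = rng.normal(0, 3, size=(8, 3))
        grid = ImageGrid((10, 10, 10), (14.0, 14.0, 14.0))
        field = tps_field(pts, disp, grid)
        # evaluate at the control points by re-fitting the interpolant directly
        from scipy.interpolate import RBFInterpolator

        vals = RBFInterpolator(pts, disp, kernel="linear", degree=1)(pts)
        assert np.allclose(vals, disp, atol=1e-6)
        assert field.displacements.shape == grid.shape + (3,)

    def test_zero_displacements_zero_field(self, rng):
        pts = rng.uniform(0, 50, size=(6, 3))
        grid = ImageGrid((6, 6, 6), (10.0, 10.0, 10.0))
        field = tps_field(pts, np.zeros((6, 3)), grid)
        assert np.allclose(field.displacements, 0.0, atol=1e-9)

    def test_matches_dense_solve_oracle(self, rng):
        pts = rng.uniform(0, 60, size=(6, 3))
        disp = rng.normal(0, 2, size=(6, 3))
        grid = ImageGrid((5, 5, 5), (15.0, 15.0, 15.0))
        field = tps_field(pts, disp, grid)
        query = grid.world_coordinates().reshape(-1, 3)
        expected = tps_oracle(pts, disp, query)
        assert np.allclose(field.displacements.reshape(-1, 3), expected, atol=1e-8)

    def test_degenerate_inputs_rejected(self, rng):
        grid = ImageGrid((4, 4, 4), (10.0, 10.0, 10.0))
        coplanar = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [10, 10, 0.0]])
        with pytest.raises(ValueError, match="coplanar"):
            tps_field(coplanar, np.zeros((4, 3)), grid)
        dup = np.array([[0, 0, 0], [0, 0, 0], [0, 10, 5], [10, 0, 5.0]])
        with pytest.raises(ValueError):
            tps_field(dup, np.zeros((4, 3)), grid)


class TestGroundTruthMapping:
    def test_zero_model_identity(self, anatomy):
        _, masks = anatomy
        model = DeformationModel(
            head_rotation_deg=0, head_translation_mm=(0, 0, 0),
            mandible_rotation_deg=0, spine_flexion_deg_per_cm=0,
            parotid_shrinkage=(0, 0), weight_loss_peak_mm=0, tps_amplitude_mm=0,
        )
        assert model.is_identity()
        field = build_ground_truth_mapping(model, masks, masks["external"].grid)
        assert np.allclose(field.displacements, 0.0, atol=1e-12)

    def test_rotation_center_is_fixed_point(self, anatomy):
        _, masks = anatomy
        grid = masks["external"].grid
        model = DeformationModel(
            head_rotation_deg=3.0, head_translation_mm=(0, 0, 0),
            mandible_rotation_deg=0, spine_flexion_deg_per_cm=0,
            parotid_shrinkage=(0, 0), weight_loss_peak_mm=0, tps_amplitude_mm=0,
        )
        field = build_ground_truth_mapping(model, masks, grid)
        coords = grid.world_coordinates()
        center = coords[masks["brainstem"].membership].mean(axis=0) + [0, 0, 25.0]
        idx = np.round(grid.world_to_index(center)).astype(int)
        # displacement at the voxel nearest the rotation center ~ 0 (sub-voxel offset)
        assert np.linalg.norm(field.displacements[tuple(idx)]) < 0.35

    def test_parotid_shrinkage_voxel_count_oracle(self, anatomy):
        """Forward-warped parotid loses the requested volume within 10%."""
        _, masks = anatomy
        grid = masks["external"].grid
        loss = 0.30
        model = DeformationModel(
            head_rotation_deg=0, head_translation_mm=(0, 0, 0),
            mandible_rotation_deg=0, spine_flexion_deg_per_cm=0,
            parotid_shrinkage=(loss, loss), weight_loss_peak_mm=0, tps_amplitude_mm=0,
        )
        field = build_ground_truth_mapping(model, masks, grid)
        for side in ("parotid_l", "parotid_r"):
            m = masks[side].membership
            jac = jacobian_determinant(field).values[m]
            assert jac.mean() < 1.0
            # voxel-counting oracle: forward-warped mask volume via inverse pull-back
            from dirqa.grid import invert_field

            inv = invert_field(field)
            warped = warp_volume(
                ScalarVolume(grid, m.astype(float)), inv, fill=0.0
            )
            vol_ratio = warped.values.sum() / m.sum()
            assert vol_ratio == pytest.approx(1.0 - loss, rel=0.10)

    def test_jacobian_positive_for_default_model(self, anatomy):
        _, masks = anatomy
        field = build_ground_truth_mapping(DeformationModel(), masks, masks["external"].grid)
        assert jacobian_determinant(field).values.min() > 0

    def test_magnitude_scales_near_linearly(self, anatomy):
        """Scaling all magnitudes by k scales mean |u| ~ linearly (within 15%)."""
        _, masks = anatomy
        grid = masks["external"].grid
        ext = masks["external"].membership
        base = DeformationModel()
        means = {}
        for k in (0.5, 1.0, 2.0):
            f = build_ground_truth_mapping(base.scaled(k), masks, grid, seed=3)
            means[k] = f.magnitude().values[ext].mean()
        assert means[0.5] == pytest.approx(0.5 * means[1.0], rel=0.15)
        assert means[2.0] == pytest.approx(2.0 * means[1.0], rel=0.15)


class TestSynthesizeEOT:
    def test_zero_field_zero_noise_identity(self, anatomy):
        vol, masks = anatomy
        eot = synthesize_eot(vol, VectorField.zero(vol.grid), noise_sd=0.0)
        assert np.allclose(eot.values, vol.values)

    def test_pure_translation_shifts_image(self, anatomy):
        vol, _ = anatomy
        grid = vol.grid
        disp = np.zeros(grid.shape + (3,))
        disp[..., 2] = grid.spacing[2]  # forward map shifts +1 voxel in z
        eot = synthesize_eot(vol, VectorField(grid, disp), noise_sd=0.0)
        # EOT(y) = SOT(y - dz): content moves superiorly by one voxel
        assert np.allclose(eot.values[:, :, 1:-1], vol.values[:, :, :-2], atol=1e-6)

    def test_noise_deterministic_given_seed(self, anatomy):
        vol, _ = anatomy
        z = VectorField.zero(vol.grid)
        e1 = synthesize_eot(vol, z, noise_sd=5.0, seed=9)
        e2 = synthesize_eot(vol, z, noise_sd=5.0, seed=9)
        assert np.array_equal(e1.values, e2.values)


class TestSynthesizeDose:
    def test_prescription_at_target_center(self, anatomy):
        _, masks = anatomy
        grid = masks["external"].grid
        center = tuple(grid.world_coordinates()[masks["external"].membership].mean(axis=0))
        dose = synthesize_dose(DosePlanSpec(target_center_mm=center), grid, masks)
        idx = tuple(np.round(grid.world_to_index(center)).astype(int))
        assert dose.values[idx] == pytest.approx(2.0)
        assert dose.values.max() == pytest.approx(2.0)

    def test_monotone_falloff_along_rays(self, anatomy):
        _, masks = anatomy
        grid = masks["external"].grid
        center = tuple(grid.world_coordinates()[masks["external"].membership].mean(axis=0))
        dose = synthesize_dose(DosePlanSpec(target_center_mm=center), grid, masks)
        ci = np.round(grid.world_to_index(center)).astype(int)
        for axis in range(3):
            line = np.moveaxis(dose.values, axis, 0)[:, ci[(axis + 1) % 3], ci[(axis + 2) % 3]]
            out = line[ci[axis]:]
            assert (np.diff(out) <= 1e-12).all()

    def test_gradient_margin_knob_lowers_oar_dose(self, anatomy):
        _, masks = anatomy
        grid = masks["external"].grid
        doses = {}
        for margin in (2.0, 20.0):
            spec = DosePlanSpec(gradient_margin_mm=margin, margin_roi="cord")
            d = synthesize_dose(spec, grid, masks)
            doses[margin] = d.values[masks["cord"].membership].mean()
        assert doses[20.0] < doses[2.0]

    def test_unachievable_margin_rejected(self, anatomy):
        _, masks = anatomy
        grid = masks["external"].grid
        spec = DosePlanSpec(gradient_margin_mm=500.0, margin_roi="cord")
        with pytest.raises(ValueError, match="margin"):
            synthesize_dose(spec, grid, masks)


class TestFullPhantom:
    def test_roundtrip_fidelity_and_invertibility(self, default_phantom):
        ph = default_phantom
        assert ph.roundtrip_nrmse < 0.02
        assert jacobian_determinant(ph.gt_field).values.min() > 0

    def test_dose_maximum_near_prescription(self, default_phantom):
        assert default_phantom.eot_dose.values.max() == pytest.approx(2.0, abs=1e-6)

    def test_deterministic_given_seed(self):
        p1 = dq.build_phantom(anatomy=SMALL, seed=4)
        p2 = dq.build_phantom(anatomy=SMALL, seed=4)
        assert np.array_equal(p1.sot.values, p2.sot.values)
        assert np.array_equal(p1.eot.values, p2.eot.values)
        assert np.array_equal(p1.gt_field.displacements, p2.gt_field.displacements)

    def test_suite_shape(self):
        suite = dq.generate_suite(n=2, anatomy=SMALL, seed=8)
        assert len(suite) == 2
        for ph in suite:
            assert set(ph.masks) == set(dq.ROI_NAMES)
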