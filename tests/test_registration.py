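import dataclasses

import numpy as np
import pytest

import lvremodel as lv
from lvremodel import AffineTransform, FFDTransform, apply_transform, nmi, transform_points
from lvremodel.exceptions import DegenerateEntropyError, ValidationError
from lvremodel.image import Volume3D
from lvremodel.registration import refine_ffd


def _noise_vol(seed, shape=(24, 24, 24), spacing=(2, 2, 2)):
    rng = np.random.default_rng(seed)
    return Volume3D(rng.uniform(0, 100, shape), spacing)


class TestNMI:
    def test_self_similarity_is_two(self):
        v = _noise_vol(0)
        assert np.isclose(nmi(v, v), 2.0, atol=1e-12)

    def test_independent_noise_near_one(self):
        a = _noise_vol(1, shape=(64, 64, 64))
        b = _noise_vol(2, shape=(64, 64, 64))
        assert abs(nmi(a, b, bins=32) - 1.0) < 0.02

    def test_intensity_shift_invariance(self):
        v = _noise_vol(3)
        shifted = v.copy_with(v.values + 12.5)
        assert abs(nmi(v, shifted) - 2.0) < 1e-6

    def test_symmetry_and_bounds(self):
        a, b = _noise_vol(4), _noise_vol(5)
        ab, ba = nmi(a, b), nmi(b, a)
        assert np.isclose(ab, ba, atol=1e-9)
        assert 1.0 <= ab <= 2.0

    def test_constant_image_degenerate(self):
        v = Volume3D(np.full((8, 8, 8), 3.0), (1, 1, 1))
        with pytest.raises(DegenerateEntropyError):
            nmi(v, _noise_vol(6, shape=(8, 8, 8), spacing=(1, 1, 1)))


class TestAffineTransform:
    def test_rigid_invariant_enforced(self):
        m = np.eye(4)
        m[0, 0] = 2.0
        with pytest.raises(ValidationError):
            AffineTransform(m, rigid=True)

    def test_points_match_matrix_multiplication(self):
        rng = np.random.default_rng(0)
        m = np.eye(4)
        m[:3, :3] = rng.normal(size=(3, 3))
        m[:3, 3] = rng.normal(size=3)
        t = AffineTransform(m)
        pts = rng.normal(size=(10, 3))
        expected = (m @ np.c_[pts, np.ones(10)].T).T[:, :3]
        assert np.allclose(transform_points(pts, t), expected, atol=1e-12)

    def test_inverse_round_trip(self):
        m = np.eye(4)
        m[:3, 3] = (4.0, -2.0, 7.0)
        t = AffineTransform(m, rigid=True)
        pts = np.random.default_rng(1).normal(size=(5, 3))
        assert np.allclose(t.inverse().map_points(t.map_points(pts)), pts, atol=1e-12)


class TestFFDTransform:
    def _lattice(self, disp=None):
        coeffs = np.zeros((6, 6, 6, 3))
        if disp is not None:
            coeffs[3, 3, 3] = disp
        return FFDTransform((-10.0, -10.0, -10.0), (10.0, 10.0, 10.0), coeffs)

    def test_identity_lattice(self):
        t = self._lattice()
        pts = np.random.default_rng(2).uniform(5, 25, (20, 3))
        assert np.allclose(t.map_points(pts), pts)

    def test_single_control_point_bspline_weight(self):
        # displace control point (3,3,3) located at 20 mm; evaluate at its site:
        # tensor weight is B1(0)^3 = (4/6)^3
        t = self._lattice(disp=(9.0, 0.0, 0.0))
        u = t.displacement([(20.0, 20.0, 20.0)])
        assert np.allclose(u[0], [9.0 * (4.0 / 6.0) ** 3, 0.0, 0.0], atol=1e-12)
        # half a cell away along x: weights B1(0.5) applied at x only
        b1_half = (3 * 0.125 - 6 * 0.25 + 4) / 6.0
        u2 = t.displacement([(25.0, 20.0, 20.0)])
        assert np.allclose(u2[0, 0], 9.0 * b1_half * (4.0 / 6.0) ** 2, atol=1e-12)

    def test_matches_simpleitk_evaluation(self):
        import SimpleITK as sitk

        from lvremodel.registration import _ffd_to_sitk

        rng = np.random.default_rng(3)
        t = FFDTransform((-12.0, -8.0, -10.0), (9.0, 11.0, 13.0), rng.normal(0, 2, (7, 6, 8, 3)))
        stx = _ffd_to_sitk(t)
        pts = rng.uniform(10, 30, (30, 3))
        mine = t.map_points(pts)
        theirs = np.array([stx.TransformPoint(tuple(p)) for p in pts])
        assert np.allclose(mine, theirs, atol=1e-9)

    def test_refinement_is_exact(self):
        rng = np.random.default_rng(4)
        t = FFDTransform((0.0, 0.0, 0.0), (8.0, 8.0, 8.0), rng.normal(0, 3, (8, 8, 8, 3)))
        fine = refine_ffd(t)
        pts = rng.uniform(12.0, 40.0, (50, 3))  # interior of both lattices
        assert np.allclose(t.displacement(pts), fine.displacement(pts), atol=1e-10)

    def test_affine_composition_order(self):
        a = AffineTransform.from_translation((5.0, 0.0, 0.0))
        t = self._lattice(disp=(9.0, 0.0, 0.0))
        t.affine = a
        p = np.array([[20.0, 20.0, 20.0]])
        assert np.allclose(t.map_points(p), p + [9.0 * (4 / 6.0) ** 3 + 5.0, 0.0, 0.0])


def test_transform_serialization_round_trip(tmp_path):
    from lvremodel.registration import affine_from_json, affine_to_json, load_ffd, save_ffd

    a = AffineTransform.from_translation((1.5, -2.0, 3.0))
    assert np.array_equal(affine_from_json(affine_to_json(a)).matrix, a.matrix)

    rng = np.random.default_rng(5)
    t = FFDTransform((-10, -10, -10), (9, 9, 9), rng.normal(0, 2, (6, 6, 6, 3)), affine=a)
    save_ffd(t, tmp_path / "ffd.nii.gz", tmp_path / "ffd.json")
    back = load_ffd(tmp_path / "ffd.nii.gz", tmp_path / "ffd.json")
    pts = rng.uniform(0, 20, (10, 3))
    assert np.allclose(back.map_points(pts), t.map_points(pts), atol=1e-5)
    assert back.affine.rigid == a.rigid


class TestApplyTransform:
    def test_identity_resample(self):
        v = _noise_vol(7)
        out = apply_transform(v, AffineTransform.identity(), v)
        assert np.allclose(out.values, v.values)

    def test_integer_voxel_shift(self):
        v = _noise_vol(8)
        t = AffineTransform.from_translation(v.spacing * [1, 0, 0])
        out = apply_transform(v, t, v)
        assert np.allclose(out.values[:-1], v.values[1:])

    def test_round_trip_small_affine(self, default_phantom):
        vol, _ = default_phantom
        m = np.eye(4)
        m[:3, 3] = (2.0, -1.5, 3.0)
        t = AffineTransform(m, rigid=True)
        there = apply_transform(vol, t, vol, background=20.0)
        back = apply_transform(there, t.inverse(), vol, background=20.0)
        interior = np.zeros(vol.shape, dtype=bool)
        interior[4:-4, 4:-4, 4:-4] = True
        mad = np.abs(back.values - vol.values)[interior].mean()
        assert mad < 12.0  # below the phantom noise sigma

    def test_consistency_with_transform_points(self):
        v = _noise_vol(9)
        t = AffineTransform.from_translation((3.0, 1.0, -2.0))
        out = apply_transform(v, t, v, background=-1.0)
        pts = v.grid_points()
        from lvremodel.image import sample_trilinear

        vals, _ = sample_trilinear(v, transform_points(pts, t), background=-1.0)
        assert np.allclose(out.values.ravel(), vals)


class TestRegisterLinear:
    def test_self_registration_is_identity(self, small_spec):
        vol, _ = lv.make_lv_phantom(small_spec)
        tx, _ = lv.register_linear(vol, vol, mode="rigid", sampling=0.25)
        assert np.abs(tx.matrix[:3, 3]).max() < 0.1
        rot_deg = np.degrees(np.arccos(np.clip((np.trace(tx.matrix[:3, :3]) - 1) / 2, -1, 1)))
        assert rot_deg < 0.1

    def test_translation_recovery(self, small_spec):
        vol, _ = lv.make_lv_phantom(small_spec)
        shift = np.array([5.0, -3.0, 8.0])
        moving = apply_transform(
            vol, AffineTransform.from_translation(-shift), vol, background=small_spec.mean_background
        )
        tx, rep = lv.register_linear(vol, moving, mode="rigid", sampling=0.25)
        assert np.all(np.abs(tx.matrix[:3, 3] - shift) < 0.5)
        assert rep.nmi_after >= rep.nmi_before

    def test_rigid_block_orthonormal_on_scaled_pair(self, small_spec):
        vol, _ = lv.make_lv_phantom(small_spec)
        scaled = dataclasses.replace(
            small_spec,
            endo_semi_axes=tuple(1.15 * np.array(small_spec.endo_semi_axes)),
            epi_semi_axes=tuple(1.15 * np.array(small_spec.epi_semi_axes)),
        )
        vol2, _ = lv.make_lv_phantom(scaled)
        tx, _ = lv.register_linear(vol, vol2, mode="rigid", sampling=0.25, max_iter=40)
        R = tx.matrix[:3, :3]
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-6)
        assert np.isclose(np.linalg.det(R), 1.0, atol=1e-6)


class TestRegisterFFD:
    def test_self_registration_near_identity(self, small_spec):
        vol, _ = lv.make_lv_phantom(small_spec)
        tx, rep = lv.register_ffd(vol, vol, lattice_spacing=20.0, levels=2, max_iter=20)
        assert tx.max_coefficient_mm() < 0.5
        assert rep.nmi_after >= rep.nmi_before

    def test_lattice_spacing_validated(self, small_spec):
        vol, _ = lv.make_lv_phantom(small_spec)
        with pytest.raises(ValidationError):
            lv.register_ffd(vol, vol, lattice_spacing=1.0)

    def test_warp_recovery_small_grid(self, small_spec):
        spec = dataclasses.replace(small_spec, expansion_factor=1.10)
        base, gt = lv.make_lv_phantom(spec)
        followup, field = lv.make_followup(base, gt, spec)
        tx, rep = lv.register_ffd(base, followup, lattice_spacing=18.0, levels=3, max_iter=40)
        wall = gt.wall_mask()
        pts = base.grid_points().reshape(base.shape + (3,))[wall]
        err = np.linalg.norm((tx.map_points(pts) - pts) - field[wall], axis=1)
        assert err.mean() < spec.spacing[0]  # under one in-plane voxel
        assert rep.nmi_after >= rep.nmi_before
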