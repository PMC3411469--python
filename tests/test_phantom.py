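import dataclasses

import numpy as np
import pytest

from lvremodel import (
    PhantomSpec,
    make_atlas,
    make_early_enhancement,
    make_followup,
    make_lge,
    make_lv_phantom,
)
from lvremodel.exceptions import ValidationError
from lvremodel.image import LABEL_LV_WALL
from lvremodel.phantom import displacement_at, shell_volume_ml


def test_invalid_specs_rejected():
    with pytest.raises(ValidationError):
        PhantomSpec(endo_semi_axes=(30, 30, 50), epi_semi_axes=(30, 32, 52))
    with pytest.raises(ValidationError):
        PhantomSpec(transmural_fraction=1.2)
    with pytest.raises(ValidationError):
        PhantomSpec(expansion_factor=-0.1)


def test_noise_free_wall_is_exactly_class_mean(noise_free_phantom):
    spec, (vol, gt) = noise_free_phantom
    wall = gt.wall_mask()
    assert np.all(vol.values[wall] == spec.mean_lv_wall)


def test_myocardial_volume_matches_analytic_shell(default_phantom, default_spec):
    _, gt = default_phantom
    measured_ml = gt.wall_mask().sum() * gt.labels.voxel_volume_mm3 / 1000.0
    analytic_ml = shell_volume_ml(default_spec)
    assert abs(measured_ml - analytic_ml) / analytic_ml < 0.05


def test_same_seed_bit_identical(default_spec):
    v1, _ = make_lv_phantom(default_spec)
    v2, _ = make_lv_phantom(default_spec)
    assert np.array_equal(v1.values, v2.values)


def test_mask_nesting_invariant(default_spec):
    spec = dataclasses.replace(default_spec, mvo=True, mvo_core_fraction=0.4)
    _, gt = make_lv_phantom(spec)
    assert gt.infarct_mask[~gt.wall_mask()].sum() == 0
    assert gt.mvo_mask[~gt.infarct_mask].sum() == 0


class TestFollowup:
    def test_identity_expansion_differs_only_by_noise(self, default_spec):
        spec = dataclasses.replace(default_spec, expansion_factor=1.0)
        base, gt = make_lv_phantom(spec)
        fu, field = make_followup(base, gt, spec)
        assert np.all(field == 0.0)
        diff = fu.values - base.values
        assert np.abs(diff).max() < 10 * spec.noise_sigma
        assert np.abs(diff.mean()) < 0.5

    def test_displacement_magnitude_at_sector_center(self, default_spec):
        s = 1.10
        spec = dataclasses.replace(default_spec, expansion_factor=s)
        c = spec.center_mm
        # mid-wall point at the sector center angle (0 deg -> +x), central z
        r = 0.5 * (spec.endo_semi_axes[0] + spec.epi_semi_axes[0])
        zmid = 0.5 * sum(spec.sector_z_mm)
        p = np.array([[c[0] + r, c[1], c[2] + zmid]])
        u = displacement_at(p, spec)
        assert np.isclose(np.linalg.norm(u), (s - 1) * r, rtol=0.01)

    def test_zero_displacement_at_sector_edges_and_outside(self, default_spec):
        spec = dataclasses.replace(default_spec, expansion_factor=1.15)
        c = spec.center_mm
        r = 26.0
        half = np.deg2rad(spec.sector_width_deg / 2.0)
        zmid = 0.5 * sum(spec.sector_z_mm)
        edge = np.array([[c[0] + r * np.cos(half), c[1] + r * np.sin(half), c[2] + zmid]])
        assert np.allclose(displacement_at(edge, spec), 0.0, atol=1e-9)
        opposite = np.array([[c[0] - r, c[1], c[2] + zmid]])
        assert np.allclose(displacement_at(opposite, spec), 0.0)

    def test_field_zero_outside_sector_support(self, default_spec):
        spec = dataclasses.replace(default_spec, expansion_factor=1.12)
        base, gt = make_lv_phantom(spec)
        _, field = make_followup(base, gt, spec)
        pts = base.grid_points()
        outside = ~gt.in_sector(pts)
        assert np.all(field.reshape(-1, 3)[outside] == 0.0)

    def test_max_displacement_linear_in_s(self, default_spec):
        maxima = []
        for s in (1.05, 1.10, 1.15):
            spec = dataclasses.replace(default_spec, expansion_factor=s)
            base, gt = make_lv_phantom(spec)
            _, field = make_followup(base, gt, spec)
            maxima.append(np.linalg.norm(field, axis=-1).max())
        ratios = np.array(maxima) / np.array([0.05, 0.10, 0.15])
        assert np.allclose(ratios, ratios[0], rtol=1e-6)


class TestLGE:
    def test_f_zero_empty_infarct(self, default_spec):
        spec = dataclasses.replace(default_spec, transmural_fraction=0.0)
        _, gt = make_lv_phantom(spec)
        assert gt.infarct_mask.sum() == 0
        lge = make_lge(gt, spec)
        wall_vals = lge.values[gt.wall_mask()]
        assert abs(wall_vals.mean() - spec.lge_remote_mean) < 3 * spec.lge_sigma

    def test_full_transmural_sector_geometric_fraction(self, default_spec):
        spec = dataclasses.replace(default_spec, transmural_fraction=1.0, sector_width_deg=60.0)
        _, gt = make_lv_phantom(spec)
        wall = gt.wall_mask()
        # restrict the comparison to the sector's long-axis slab
        z = np.arange(spec.shape[2]) * spec.spacing[2] - spec.center_mm[2]
        slab = (z >= spec.sector_z_mm[0]) & (z <= spec.sector_z_mm[1])
        frac = gt.infarct_mask[:, :, slab].sum() / wall[:, :, slab].sum()
        assert abs(frac - 60.0 / 360.0) < 0.05 * (60.0 / 360.0) + 0.01


class TestEarlyEnhancement:
    def test_mvo_flag_off_empty(self, default_spec):
        spec = dataclasses.replace(default_spec, mvo=False)
        _, gt = make_lv_phantom(spec)
        make_early_enhancement(gt, spec)
        assert gt.mvo_mask.sum() == 0

    def test_core_fraction_half(self, default_spec):
        spec = dataclasses.replace(default_spec, mvo=True, mvo_core_fraction=0.5, transmural_fraction=0.8)
        _, gt = make_lv_phantom(spec)
        ratio = gt.mvo_mask.sum() / gt.infarct_mask.sum()
        assert abs(ratio - 0.5) <= 0.05


class TestAtlas:
    def test_probabilities_sum_to_one(self, default_spec):
        atlas = make_atlas(default_spec, blur_sigma_vox=1.0)
        assert np.allclose(atlas.probabilities.sum(axis=0), 1.0, atol=1e-9)

    def test_zero_blur_gives_indicators(self, default_spec):
        atlas = make_atlas(default_spec, blur_sigma_vox=0.0)
        assert set(np.unique(atlas.probabilities)) <= {0.0, 1.0}

    def test_deep_blood_pool_probability(self, default_spec):
        atlas = make_atlas(default_spec, blur_sigma_vox=1.0)
        _, gt = make_lv_phantom(dataclasses.replace(default_spec, noise_sigma=0.0))
        from scipy.ndimage import binary_erosion

        deep = binary_erosion(gt.labels.mask(1), iterations=4)
        assert atlas.probabilities[1][deep].min() > 0.99


def test_subject_round_trip(tmp_path, default_spec):
    from lvremodel.phantom import make_subject, read_subject, write_subject

    spec = dataclasses.replace(default_spec, mvo=True, expansion_factor=1.08)
    subject = make_subject(spec, "s1")
    write_subject(subject, tmp_path / "s1")
    back = read_subject(tmp_path / "s1")
    assert np.allclose(back.baseline.values, subject.baseline.values, atol=1e-3)
    assert np.array_equal(back.gt.labels.labels, subject.gt.labels.labels)
    assert np.array_equal(back.gt.infarct_mask, subject.gt.infarct_mask)
    assert np.allclose(back.gt.displacement_field, subject.gt.displacement_field, atol=1e-4)
    assert back.spec == subject.spec
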