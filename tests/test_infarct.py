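import dataclasses

import numpy as np
import pytest

from lvremodel import (
    Volume3D,
    classify_infarct,
    detect_mvo,
    extract_surfaces,
    fit_gmm2,
    infarct_size,
    make_early_enhancement,
    make_lge,
    make_lv_phantom,
    transmural_extent,
)
from lvremodel.exceptions import ValidationError
from lvremodel.segmentation import dice


class TestFitGMM2:
    def test_recovers_generating_parameters(self):
        rng = np.random.default_rng(42)
        n = 5000
        comp = rng.uniform(size=n) < 0.3
        x = np.where(comp, rng.normal(80.0, 8.0, n), rng.normal(30.0, 5.0, n))
        gmm = fit_gmm2(x)
        assert abs(gmm.means[0] - 30.0) < 1.0
        assert abs(gmm.means[1] - 80.0) < 1.0
        assert abs(gmm.weights[1] - 0.3) < 0.03
        lls = np.array(gmm.log_likelihoods)
        assert np.all(np.diff(lls) >= -1e-7 * np.abs(lls[:-1]))

    def test_interleaved_constants(self):
        x = np.array([10.0, 90.0] * 50)
        gmm = fit_gmm2(x)
        assert np.allclose(gmm.means, [10.0, 90.0])
        assert gmm.variances.max() < 1e-2  # at floor

    def test_unimodal_warning(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="unimodal"):
            gmm = fit_gmm2(rng.normal(50.0, 5.0, 4000))
        assert gmm.unimodal_warning

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            fit_gmm2(np.full(100, 3.0))

    def test_matches_sklearn_on_shared_data(self):
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(40, 6, 3000), rng.normal(120, 10, 1500)])
        mine = fit_gmm2(x)
        sk = GaussianMixture(2, means_init=[[40.0], [120.0]], random_state=0, tol=1e-8, max_iter=500).fit(
            x.reshape(-1, 1)
        )
        order = np.argsort(sk.means_.ravel())
        assert np.allclose(mine.means, sk.means_.ravel()[order], atol=0.2)
        assert np.allclose(mine.weights, sk.weights_[order], atol=0.01)


class TestClassifyInfarct:
    def test_component_means_classified(self):
        gmm = fit_gmm2(np.concatenate([np.random.default_rng(1).normal(30, 5, 2000),
                                       np.random.default_rng(2).normal(100, 8, 2000)]))
        vol = Volume3D(np.full((4, 4, 4), gmm.means[1]), (1, 1, 1))
        myo = np.ones((4, 4, 4), dtype=bool)
        assert classify_infarct(vol, myo, gmm).all()
        vol_low = Volume3D(np.full((4, 4, 4), gmm.means[0]), (1, 1, 1))
        assert not classify_infarct(vol_low, myo, gmm).any()

    def test_phantom_dice(self, default_spec):
        spec = dataclasses.replace(default_spec, transmural_fraction=0.5)
        _, gt = make_lv_phantom(spec)
        lge = make_lge(gt, spec)
        myo = gt.wall_mask()
        gmm = fit_gmm2(lge.values[myo])
        mask = classify_infarct(lge, myo, gmm)
        assert dice(mask, gt.infarct_mask) >= 0.85


class TestTransmuralExtent:
    @pytest.fixture(scope="class")
    def meshes_and_gt(self, default_spec):
        spec = dataclasses.replace(default_spec, transmural_fraction=0.5, noise_sigma=0.0)
        _, gt = make_lv_phantom(spec)
        endo, epi = extract_surfaces(gt.labels)
        return spec, gt, endo, epi

    def test_no_infarct_gives_zero(self, meshes_and_gt):
        spec, gt, endo, epi = meshes_and_gt
        extent = transmural_extent(np.zeros_like(gt.infarct_mask), gt.wall_mask(), epi, endo,
                                   gt.labels.as_volume())
        assert np.nanmax(extent) == 0.0

    def test_extent_in_unit_interval(self, meshes_and_gt):
        spec, gt, endo, epi = meshes_and_gt
        extent = transmural_extent(gt.infarct_mask, gt.wall_mask(), epi, endo, gt.labels.as_volume())
        ok = np.isfinite(extent)
        assert ok.any()
        assert extent[ok].min() >= 0.0 and extent[ok].max() <= 1.0

    def test_recovery_at_f_half(self, meshes_and_gt):
        spec, gt, endo, epi = meshes_and_gt
        extent = transmural_extent(gt.infarct_mask, gt.wall_mask(), epi, endo, gt.labels.as_volume())
        interior = gt.in_sector(epi.vertices, angle_margin_deg=12.0, z_margin_mm=10.0)
        vals = extent[interior & np.isfinite(extent)]
        assert vals.size > 10
        assert abs(vals.mean() - 0.5) < 0.1

    def test_monotone_in_f(self, default_spec):
        means = []
        for f in (0.25, 0.5, 0.75, 1.0):
            spec = dataclasses.replace(default_spec, transmural_fraction=f, noise_sigma=0.0)
            _, gt = make_lv_phantom(spec)
            endo, epi = extract_surfaces(gt.labels)
            extent = transmural_extent(gt.infarct_mask, gt.wall_mask(), epi, endo, gt.labels.as_volume())
            interior = gt.in_sector(epi.vertices, angle_margin_deg=12.0, z_margin_mm=10.0)
            means.append(np.nanmean(extent[interior]))
        assert np.all(np.diff(means) > 0)


class TestMVO:
    def test_phantom_core_recovered(self, default_spec):
        spec = dataclasses.replace(default_spec, mvo=True, mvo_core_fraction=0.5, transmural_fraction=0.8)
        _, gt = make_lv_phantom(spec)
        early = make_early_enhancement(gt, spec)
        mvo, present = detect_mvo(early, gt.infarct_mask, gt.wall_mask())
        assert present
        assert dice(mvo, gt.mvo_mask) >= 0.8

    def test_no_mvo_phantom(self, default_spec):
        spec = dataclasses.replace(default_spec, mvo=False)
        _, gt = make_lv_phantom(spec)
        early = make_early_enhancement(gt, spec)
        mvo, present = detect_mvo(early, gt.infarct_mask, gt.wall_mask())
        assert not present

    def test_empty_infarct(self, default_spec):
        _, gt = make_lv_phantom(default_spec)
        early = make_early_enhancement(gt, default_spec)
        mvo, present = detect_mvo(early, np.zeros_like(gt.infarct_mask), gt.wall_mask())
        assert not present and not mvo.any()

    def test_mvo_subset_of_infarct(self, default_spec):
        spec = dataclasses.replace(default_spec, mvo=True, transmural_fraction=0.7)
        _, gt = make_lv_phantom(spec)
        early = make_early_enhancement(gt, spec)
        mvo, _ = detect_mvo(early, gt.infarct_mask, gt.wall_mask())
        assert not np.any(mvo & ~gt.infarct_mask)


class TestInfarctSize:
    def test_edge_cases(self):
        myo = np.zeros((4, 4, 4), dtype=bool)
        myo[1:3, 1:3, 1:3] = True
        assert infarct_size(np.zeros_like(myo), myo, (1, 1, 1)) == 0.0
        assert infarct_size(myo, myo, (1, 1, 1)) == 100.0
        with pytest.raises(ValidationError):
            infarct_size(myo, np.zeros_like(myo), (1, 1, 1))

    def test_phantom_geometric_fraction(self, default_spec):
        spec = dataclasses.replace(default_spec, transmural_fraction=1.0)
        _, gt = make_lv_phantom(spec)
        lge = make_lge(gt, spec)
        myo = gt.wall_mask()
        gmm = fit_gmm2(lge.values[myo])
        mask = classify_infarct(lge, myo, gmm)
        truth_pct = 100.0 * gt.infarct_mask.sum() / myo.sum()
        assert abs(infarct_size(mask, myo, spec.spacing) - truth_pct) < 2.0
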