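import dataclasses

import numpy as np
import pytest

from lvremodel import PhantomSpec, make_lv_phantom


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec(seed=11)


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    return make_lv_phantom(default_spec)


@pytest.fixture(scope="session")
def noise_free_phantom():
    spec = dataclasses.replace(PhantomSpec(seed=11), noise_sigma=0.0)
    return spec, make_lv_phantom(spec)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A reduced grid for registration-heavy tests."""
    return PhantomSpec(
        shape=(40, 40, 40),
        spacing=(2.8, 2.8, 3.6),
        seed=5,
    )


def reduced_regional_remodeling(expansion: float, i: int, seed: int = 0) -> tuple[float, float]:
    """Infarct- and remote-region mean remodeling for one reduced-size subject.

    Runs the statistic-producing chain (rigid alignment, EM segmentation of
    both time points, segmentation-guided FFD, neighbor-separation statistic)
    on a 36-cube phantom; the reference-geometry atlas serves directly as the
    spatial prior and the ground-truth infarct mask stands in for the GMM
    stage.  Geometry, sector orientation, transmural fraction and both noise
    draws vary with ``i``.
    """
    from scipy.ndimage import binary_dilation, gaussian_filter

    from lvremodel import (
        PhantomSpec,
        apply_transform,
        em_segment,
        extract_surfaces,
        local_remodeling,
        make_atlas,
        make_followup,
        register_ffd,
        register_linear,
        transmural_extent,
    )
    from lvremodel.image import LABEL_LV_WALL

    rng = np.random.default_rng([seed, 9000 + i])
    scale = 1.0 + 0.08 * rng.uniform(-1.0, 1.0)
    spec = PhantomSpec(
        shape=(36, 36, 36),
        spacing=(3.1, 3.1, 4.0),
        endo_semi_axes=tuple(np.array((22.0, 22.0, 40.0)) * scale),
        epi_semi_axes=tuple(np.array((30.0, 30.0, 48.0)) * scale),
        sector_center_deg=float(rng.uniform(0.0, 360.0)),
        transmural_fraction=float(rng.uniform(0.3, 1.0)),
        expansion_factor=expansion,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    base, gt = make_lv_phantom(spec)
    followup, _ = make_followup(base, gt, spec)
    atlas = make_atlas(
        dataclasses.replace(spec, endo_semi_axes=(22.0, 22.0, 40.0), epi_semi_axes=(30.0, 30.0, 48.0)),
        1.0,
    )
    posterior_b, model_b = em_segment(base, atlas)
    t_rigid, _ = register_linear(base, followup, mode="rigid", sampling=0.25)
    followup_res = apply_transform(
        followup, t_rigid, base, background=float(np.percentile(base.values, 1))
    )
    posterior_f, model_f = em_segment(followup_res, atlas)

    def soft(post, model):
        return base.copy_with(
            gaussian_filter(np.einsum("k,k...->...", model.means, post.posteriors), 1.0)
        )

    labels = posterior_b.labels
    myo = labels.mask(LABEL_LV_WALL)
    endo, epi = extract_surfaces(labels)
    mask = binary_dilation(myo, iterations=2)
    tx, _ = register_ffd(
        soft(posterior_b, model_b), soft(posterior_f, model_f),
        lattice_spacing=18.0, levels=2, max_iter=10, mask=mask,
    )
    rm = local_remodeling(epi, tx)
    extent = transmural_extent(gt.infarct_mask, myo, epi, endo, gt.labels.as_volume())
    ok = np.isfinite(rm) & np.isfinite(extent)
    return float(rm[ok & (extent > 0)].mean()), float(rm[ok & (extent == 0)].mean())


def sphere_labels(r_endo=20.0, r_epi=30.0, spacing=1.2, n=60):
    """Concentric-sphere shell label volume (LV blood inside endo, wall between)."""
    from lvremodel import LabelVolume

    ax = (np.arange(n) - (n - 1) / 2) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    labels = np.zeros((n, n, n), dtype=np.uint8)
    labels[r < r_endo] = 1
    labels[(r >= r_endo) & (r <= r_epi)] = 2
    return LabelVolume(labels, (spacing,) * 3, (0.0, 0.0, 0.0))
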