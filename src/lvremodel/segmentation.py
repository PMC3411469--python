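"""Probabilistic-atlas alignment and EM segmentation of the left ventricle.

The atlas assigns every voxel a prior probability of being background, LV
blood pool, LV wall, or RV blood pool.  After aligning the atlas to a target
volume (affine then free-form registration of the atlas's intensity
template), the target is segmented by expectation-maximization with Gaussian
class intensities and the warped atlas as a spatial prior:

* E-step: ``posterior_k(x) ∝ prior_k(x) · N(I(x); mu_k, sigma_k^2)``
* M-step: ``mu_k``, ``sigma_k^2`` re-estimated as posterior-weighted mean and
  variance.

Mixing weights are absorbed into the spatial prior when an atlas is supplied;
with a uniform prior the same routine degenerates to a plain Gaussian-mixture
classifier with learned weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import ValidationError
from .image import LabelVolume, Volume3D, read_volume, write_volume
from .registration import SimilarityReport, apply_transform, register_ffd, register_linear

CLASS_NAMES = ("background", "lv_blood", "lv_wall", "rv_blood")


@dataclass
class ProbabilisticAtlas:
    """Four co-registered probability fields summing to 1 per voxel, plus an intensity template."""

    probabilities: np.ndarray  # (4, nx, ny, nz)
    spacing: np.ndarray
    origin: np.ndarray
    template: Volume3D

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if self.probabilities.ndim != 4 or self.probabilities.shape[0] != 4:
            raise ValidationError("atlas probabilities must have shape (4, nx, ny, nz)")
        if self.probabilities.min() < -1e-9 or self.probabilities.max() > 1 + 1e-9:
            raise ValidationError("atlas probabilities must lie in [0, 1]")
        total = self.probabilities.sum(axis=0)
        if not np.allclose(total, 1.0, atol=1e-6):
            raise ValidationError("atlas probabilities must sum to 1 per voxel (within 1e-6)")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.probabilities.shape[1:]  # type: ignore[return-value]

    def field(self, k: int) -> Volume3D:
        return Volume3D(self.probabilities[k], self.spacing.copy(), self.origin.copy())

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for k, name in enumerate(CLASS_NAMES):
            write_volume(self.field(k), d / f"prob_{name}.nii.gz")
        write_volume(self.template, d / "template.nii.gz")
        (d / "manifest.json").write_text(json.dumps({"classes": list(CLASS_NAMES)}))

    @classmethod
    def load(cls, directory) -> "ProbabilisticAtlas":
        d = Path(directory)
        fields = [read_volume(d / f"prob_{name}.nii.gz") for name in CLASS_NAMES]
        template = read_volume(d / "template.nii.gz")
        probs = np.stack([f.values for f in fields], axis=0)
        total = probs.sum(axis=0)
        total[total == 0] = 1.0
        return cls(probs / total, fields[0].spacing, fields[0].origin, template)


@dataclass
class ClassModel:
    """Per-class Gaussian intensity parameters (and mixing weights in uniform-prior mode)."""

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    dropped: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.variances <= 0):
            raise ValidationError("class variances must be > 0")
        if np.any(self.weights < 0):
            raise ValidationError("class weights must be >= 0")


@dataclass
class PosteriorMap:
    """Per-voxel class posteriors and the argmax hard labels."""

    posteriors: np.ndarray  # (K, nx, ny, nz)
    labels: LabelVolume
    log_likelihoods: list[float]
    converged: bool
    n_iter: int


def align_atlas(
    atlas: ProbabilisticAtlas,
    target: Volume3D,
    use_ffd: bool = True,
    lattice_spacing: float = 24.0,
    bins: int = 32,
    max_iter: int = 100,
    levels: int = 2,
    sampling: float = 1.0,
) -> tuple[ProbabilisticAtlas, SimilarityReport]:
    """Warp the atlas onto a target volume via affine (then optionally FFD) registration
    of the atlas intensity template, resampling and renormalizing the probability fields.
    """
    affine, report = register_linear(
        target, atlas.template, mode="affine", bins=bins, max_iter=max_iter, sampling=sampling
    )
    transform = affine
    if use_ffd:
        transform, report = register_ffd(
            target,
            atlas.template,
            init=affine,
            lattice_spacing=lattice_spacing,
            bins=bins,
            max_iter=max_iter,
            levels=levels,
            sampling=sampling,
        )
    if not report.converged:
        warnings.warn("atlas registration did not converge; returning best available alignment")

    warped = np.empty((4,) + target.shape, dtype=np.float64)
    for k in range(4):
        bg = 1.0 if k == 0 else 0.0  # outside the atlas domain is background
        warped[k] = apply_transform(atlas.field(k), transform, target, background=bg).values
    warped = np.clip(warped, 0.0, None)
    total = warped.sum(axis=0)
    zero = total <= 0
    warped[0, zero] = 1.0
    total[zero] = 1.0
    warped /= total
    template_w = apply_transform(atlas.template, transform, target, background=0.0)
    return ProbabilisticAtlas(warped, target.spacing.copy(), target.origin.copy(), template_w), report


def _log_normal_pdf(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def em_segment(
    target: Volume3D,
    prior: ProbabilisticAtlas | None,
    max_iter: int = 100,
    tol: float | None = None,
    n_classes: int = 4,
) -> tuple[PosteriorMap, ClassModel]:
    """EM segmentation with Gaussian class intensities and atlas spatial priors.

    With ``prior=None`` a uniform prior is used, mixing weights are learned,
    and the routine reduces to ordinary Gaussian-mixture classification
    (initialized by quantile split, like the infarct GMM fitter).

    The posterior-weighted log-likelihood is non-decreasing across iterations;
    convergence when the largest class-mean change drops below ``tol``
    (default 0.1% of the target intensity range).
    """
    intensities = target.values.ravel()
    rng_range = float(intensities.max() - intensities.min())
    if rng_range <= 0:
        raise ValidationError("constant target image; nothing to segment")
    if tol is None:
        tol = 1e-3 * rng_range
    var_floor = max(1e-6 * rng_range**2, 1e-12)

    if prior is not None:
        if prior.shape != target.shape:
            raise ValidationError("prior must be aligned to (resampled on) the target grid")
        K = prior.probabilities.shape[0]
        P = prior.probabilities.reshape(K, -1)
        learn_weights = False
    else:
        K = n_classes
        P = np.full((K, intensities.size), 1.0 / K)
        learn_weights = True

    weights = np.full(K, 1.0 / K)
    dropped = [k for k in range(K) if P[k].sum() == 0]
    if dropped:
        warnings.warn(f"classes {dropped} have zero total prior mass and are dropped")

    # initialization
    means = np.zeros(K)
    variances = np.full(K, var_floor)
    if prior is not None:
        for k in range(K):
            mass = P[k].sum()
            if mass > 0:
                means[k] = (P[k] * intensities).sum() / mass
                variances[k] = max((P[k] * (intensities - means[k]) ** 2).sum() / mass, var_floor)
    else:
        # quantile-split initialization (deterministic)
        qs = np.quantile(intensities, np.linspace(0, 1, K + 1))
        for k in range(K):
            lo, hi = qs[k], qs[k + 1]
            sel = (intensities >= lo) & (intensities <= hi if k == K - 1 else intensities < hi)
            chunk = intensities[sel]
            if chunk.size:
                means[k] = chunk.mean()
                variances[k] = max(chunk.var(), var_floor)
            weights[k] = max(chunk.size, 1) / intensities.size

    log_likelihoods: list[float] = []
    converged = False
    post = np.zeros((K, intensities.size))
    it = 0
    for it in range(1, max_iter + 1):
        # E-step in log space; zero prior annihilates the posterior exactly
        with np.errstate(divide="ignore"):
            logp = np.log(P) + np.log(weights)[:, None] if learn_weights else np.log(P)
        for k in range(K):
            if k in dropped:
                logp[k] = -np.inf
            else:
                logp[k] = logp[k] + _log_normal_pdf(intensities, means[k], variances[k])
        mx = logp.max(axis=0)
        bad = ~np.isfinite(mx)
        mx_safe = np.where(bad, 0.0, mx)
        with np.errstate(invalid="ignore"):
            expd = np.exp(logp - mx_safe)
        expd[:, bad] = 0.0
        total = expd.sum(axis=0)
        ll = float(np.sum(mx_safe[~bad] + np.log(total[~bad])))
        log_likelihoods.append(ll)
        safe_total = np.where(total > 0, total, 1.0)
        post = expd / safe_total

        # M-step
        new_means = means.copy()
        for k in range(K):
            if k in dropped:
                continue
            mass = post[k].sum()
            if mass <= 0:
                continue
            new_means[k] = (post[k] * intensities).sum() / mass
            v = (post[k] * (intensities - new_means[k]) ** 2).sum() / mass
            if v < var_floor:
                warnings.warn(f"variance collapse in class {k}; floored")
                v = var_floor
            variances[k] = v
            if learn_weights:
                weights[k] = mass / intensities.size
        if learn_weights:
            weights = weights / weights.sum()
        delta = float(np.max(np.abs(new_means - means)))
        means = new_means
        if delta < tol:
            converged = True
            break

    hard = np.argmax(post, axis=0).astype(np.uint8)  # ties -> lowest class code
    labels = LabelVolume(hard.reshape(target.shape), target.spacing.copy(), target.origin.copy())
    pm = PosteriorMap(
        posteriors=post.reshape((K,) + target.shape),
        labels=labels,
        log_likelihoods=log_likelihoods,
        converged=converged,
        n_iter=it,
    )
    return pm, ClassModel(means, variances, weights, dropped)


def _point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distances from points (N,3) to triangles (N,3,3), paired per row."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    def take(cond, value):
        sel = cond & ~done
        closest[sel] = value[sel] if value.ndim == 2 else value
        done[sel] = True

    take((d1 <= 0) & (d2 <= 0), a)  # vertex a
    take((d3 >= 0) & (d4 <= d3), b)  # vertex b
    take((d6 >= 0) & (d5 <= d6), c)  # vertex c
    vc = d1 * d4 - d3 * d2
    with np.errstate(invalid="ignore", divide="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    take((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)  # edge ab
    vb = d5 * d2 - d1 * d6
    with np.errstate(invalid="ignore", divide="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    take((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)  # edge ac
    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
    take((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + w_bc[:, None] * (c - b))  # edge bc
    total = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(total != 0, vb / total, 0.0)
        w = np.where(total != 0, vc / total, 0.0)
    take(np.ones(len(points), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)  # interior
    return np.linalg.norm(points - closest, axis=1)


def _vertices_to_surface(points: np.ndarray, mesh, k: int = 12) -> np.ndarray:
    """Distance from each point to the nearest point on the mesh surface."""
    tris = mesh.vertices[mesh.faces]  # (F, 3, 3)
    centroids = tris.mean(axis=1)
    kq = min(k, len(centroids))
    _, cand = cKDTree(centroids).query(points, k=kq)
    cand = np.atleast_2d(cand.T).T if kq == 1 else cand
    best = np.full(len(points), np.inf)
    for j in range(kq):
        d = _point_triangle_distance(points, tris[cand[:, j]])
        best = np.minimum(best, d)
    return best


def surface_distance(a, b) -> float:
    """Symmetric mean surface-to-surface distance (mm) between two meshes.

    Mean of vertex-to-nearest-surface-point distances a->b and b->a, averaged.
    """
    for mesh, name in ((a, "a"), (b, "b")):
        if len(mesh.vertices) == 0 or len(mesh.faces) == 0:
            raise ValidationError(f"mesh {name} is empty")
    d_ab = _vertices_to_surface(np.asarray(a.vertices, dtype=float), b)
    d_ba = _vertices_to_surface(np.asarray(b.vertices, dtype=float), a)
    return float(0.5 * (d_ab.mean() + d_ba.mean()))


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap coefficient of two boolean masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
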