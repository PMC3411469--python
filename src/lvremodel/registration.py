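"""Intensity-based rigid, affine and free-form-deformation (FFD) registration.

Similarity is the Studholme normalized mutual information (NMI),
``(H(A) + H(B)) / H(A, B)``, bounded in [1, 2].  Rigid/affine transforms are
optimized with SimpleITK's multi-resolution registration framework; the
free-form deformation is optimized by an in-package deterministic coordinate
search that maximizes NMI directly (with incremental joint-histogram updates)
under a bending-energy penalty — greedy acceptance means deformation modes
the intensities cannot constrain are never introduced.  Transforms are plain,
exactly-evaluable types:

* :class:`AffineTransform` — a 4x4 homogeneous matrix in world mm, with an
  optional rigid restriction (orthonormal 3x3 block, det +1);
* :class:`FFDTransform` — cubic B-spline displacements on a regular control
  lattice, ``T(x) = A(x + u(x))`` with the displacement u evaluated exactly
  from the 4x4x4 surrounding control coefficients (no grid interpolation).

Both registrations guarantee the returned transform never has a lower masked
NMI than their initialization: if the optimizer ends worse, the
initialization is returned with ``converged=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

from .exceptions import DegenerateEntropyError, ValidationError
from .image import Volume3D, sample_trilinear

# single-threaded ITK: bit-reproducible metric reductions
sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(1)

# ---------------------------------------------------------------------------
# transform types
# ---------------------------------------------------------------------------


@dataclass
class AffineTransform:
    """4x4 homogeneous world-coordinate (mm) transform; optionally rigid."""

    matrix: np.ndarray
    rigid: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (4, 4):
            raise ValidationError(f"affine matrix must be 4x4, got {self.matrix.shape}")
        if not np.allclose(self.matrix[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise ValidationError("last row of a homogeneous transform must be (0,0,0,1)")
        if self.rigid:
            R = self.matrix[:3, :3]
            if not np.allclose(R @ R.T, np.eye(3), atol=1e-6) or not np.isclose(
                np.linalg.det(R), 1.0, atol=1e-6
            ):
                raise ValidationError("rigid flag set but 3x3 block is not a proper rotation")

    @classmethod
    def identity(cls, rigid: bool = True) -> "AffineTransform":
        return cls(np.eye(4), rigid=rigid)

    @classmethod
    def from_translation(cls, t, rigid: bool = True) -> "AffineTransform":
        m = np.eye(4)
        m[:3, 3] = np.asarray(t, dtype=float)
        return cls(m, rigid=rigid)

    def map_points(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), rigid=self.rigid)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return self o other (other applied first)."""
        return AffineTransform(self.matrix @ other.matrix, rigid=self.rigid and other.rigid)

    def to_sitk(self) -> sitk.AffineTransform:
        tx = sitk.AffineTransform(3)
        tx.SetMatrix(self.matrix[:3, :3].ravel().tolist())
        tx.SetTranslation(self.matrix[:3, 3].tolist())
        return tx


def _bspline_weights(f: np.ndarray) -> list[np.ndarray]:
    """Cubic B-spline basis values for fractional offsets f in [0, 1)."""
    f2 = f * f
    f3 = f2 * f
    return [
        (1.0 - f) ** 3 / 6.0,
        (3.0 * f3 - 6.0 * f2 + 4.0) / 6.0,
        (-3.0 * f3 + 3.0 * f2 + 3.0 * f + 1.0) / 6.0,
        f3 / 6.0,
    ]


@dataclass
class FFDTransform:
    """Free-form deformation: cubic B-spline displacements on a control lattice.

    The displacement at a world point x is the tensor-product B-spline sum of
    the 4x4x4 surrounding control coefficients.  Points outside the lattice's
    valid support are extrapolated with the edge coefficient window (with a
    warning).  If an affine prealignment is attached, the full map is
    ``T(x) = A(x + u(x))``.
    """

    lattice_origin: np.ndarray  # world position of control point (0,0,0)
    lattice_spacing: np.ndarray  # mm between control points
    coefficients: np.ndarray  # (nx, ny, nz, 3) displacements, mm
    affine: AffineTransform | None = None

    def __post_init__(self) -> None:
        self.lattice_origin = np.asarray(self.lattice_origin, dtype=float).reshape(3)
        self.lattice_spacing = np.asarray(self.lattice_spacing, dtype=float).reshape(3)
        if not np.all(self.lattice_spacing > 0):
            raise ValidationError("lattice spacing must be strictly positive")
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.ndim != 4 or self.coefficients.shape[-1] != 3:
            raise ValidationError("coefficients must have shape (nx, ny, nz, 3)")
        if min(self.coefficients.shape[:3]) < 4:
            raise ValidationError("cubic B-spline lattice needs at least 4 control points per axis")

    @property
    def lattice_shape(self) -> tuple[int, int, int]:
        return self.coefficients.shape[:3]  # type: ignore[return-value]

    def displacement(self, points) -> np.ndarray:
        """Exact cubic B-spline displacement u(x) at world points, shape (N, 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        s = (pts - self.lattice_origin) / self.lattice_spacing
        i = np.floor(s).astype(int)
        shape = np.asarray(self.lattice_shape)
        lo, hi = 1, shape - 3  # valid range for the window start i-1 .. i+2
        clamped = np.clip(i, lo, hi)
        if np.any(clamped != i):
            warnings.warn(
                "points outside the FFD lattice support; extrapolating with edge coefficients",
                stacklevel=2,
            )
        f = s - clamped
        wx = _bspline_weights(f[:, 0])
        wy = _bspline_weights(f[:, 1])
        wz = _bspline_weights(f[:, 2])
        out = np.zeros_like(pts)
        ii, jj, kk = clamped[:, 0], clamped[:, 1], clamped[:, 2]
        ny, nz = int(shape[1]), int(shape[2])
        flat = self.coefficients.reshape(-1, 3)
        for l in range(4):
            ix = (ii - 1 + l) * ny
            for m in range(4):
                ixy = (ix + (jj - 1 + m)) * nz
                w_lm = wx[l] * wy[m]
                for n in range(4):
                    out += (w_lm * wz[n])[:, None] * flat[ixy + (kk - 1 + n)]
        return out

    def map_points(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        y = pts + self.displacement(pts)
        if self.affine is not None:
            y = self.affine.map_points(y)
        return y

    def max_coefficient_mm(self) -> float:
        return float(np.linalg.norm(self.coefficients, axis=-1).max())


@dataclass
class SimilarityReport:
    """NMI before/after a registration, iteration count, and convergence flag."""

    nmi_before: float
    nmi_after: float
    iterations: int
    converged: bool

    def __post_init__(self) -> None:
        for v in (self.nmi_before, self.nmi_after):
            if not (1.0 - 1e-9 <= v <= 2.0 + 1e-9):
                raise ValidationError(f"NMI values must lie in [1, 2], got {v}")


# ---------------------------------------------------------------------------
# normalized mutual information
# ---------------------------------------------------------------------------


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def nmi(a: Volume3D, b: Volume3D, bins: int = 64, mask: np.ndarray | None = None) -> float:
    """Studholme normalized mutual information (H(A)+H(B))/H(A,B) in [1, 2].

    Joint histogram with ``bins**2`` cells; each image is binned linearly
    between its masked 1st and 99th intensity percentiles (values outside are
    clipped into the edge bins).  Raises
    :class:`~lvremodel.exceptions.DegenerateEntropyError` on a constant image.
    """
    if not a.same_grid(b):
        raise ValidationError("nmi requires both volumes on the same grid; resample first")
    av = a.values.ravel()
    bv = b.values.ravel()
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        av, bv = av[m], bv[m]
    if av.size == 0:
        raise ValidationError("empty mask")

    def edges(x):
        lo, hi = np.percentile(x, [1.0, 99.0])
        if hi <= lo:
            lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            raise DegenerateEntropyError("constant image within mask; entropy undefined")
        return np.linspace(lo, hi, bins + 1)

    ea, eb = edges(av), edges(bv)
    h, _, _ = np.histogram2d(np.clip(av, ea[0], ea[-1]), np.clip(bv, eb[0], eb[-1]), bins=[ea, eb])
    p = h / h.sum()
    ha = _entropy(p.sum(axis=1))
    hb = _entropy(p.sum(axis=0))
    hab = _entropy(p.ravel())
    if hab == 0.0:
        raise DegenerateEntropyError("joint entropy is zero; images are constant within mask")
    return (ha + hb) / hab


# ---------------------------------------------------------------------------
# SimpleITK bridge
# ---------------------------------------------------------------------------


def _to_sitk(vol: Volume3D, dtype=np.float32) -> sitk.Image:
    arr = np.ascontiguousarray(vol.values.transpose(2, 1, 0).astype(dtype))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    return img


def _mask_to_sitk(mask: np.ndarray, like: Volume3D) -> sitk.Image:
    arr = np.ascontiguousarray(mask.astype(np.uint8).transpose(2, 1, 0))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in like.spacing))
    img.SetOrigin(tuple(float(o) for o in like.origin))
    return img


def _affine_from_sitk(tx) -> np.ndarray:
    """4x4 matrix for a sitk transform with matrix/center/translation parameterization."""
    M = np.asarray(tx.GetMatrix(), dtype=float).reshape(3, 3)
    c = np.asarray(tx.GetCenter(), dtype=float)
    t = np.asarray(tx.GetTranslation(), dtype=float)
    out = np.eye(4)
    out[:3, :3] = M
    out[:3, 3] = c + t - M @ c
    return out


def _orthonormalize(M: np.ndarray) -> np.ndarray:
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    return R


def _masked_nmi(fixed: Volume3D, moved: Volume3D, inside: np.ndarray, mask: np.ndarray | None, bins: int) -> float:
    m = inside if mask is None else (inside & np.asarray(mask, dtype=bool))
    return nmi(fixed, moved, bins=bins, mask=m)


# ---------------------------------------------------------------------------
# resampling through transforms
# ---------------------------------------------------------------------------


def transform_points(points, t) -> np.ndarray:
    """Map world points through an affine, FFD, or plain callable transform."""
    if hasattr(t, "map_points"):
        return t.map_points(points)
    if callable(t):
        return np.atleast_2d(np.asarray(t(points), dtype=float))
    raise ValidationError(f"unsupported transform type {type(t)!r}")


def apply_transform(
    vol: Volume3D,
    t,
    reference: Volume3D,
    background: float = 0.0,
    return_inside: bool = False,
):
    """Resample ``vol`` onto the reference grid through transform t (fixed -> moving).

    Out-of-domain samples get ``background``.  With ``return_inside`` the
    in-domain boolean field is returned alongside, so similarity metrics can
    ignore flagged samples.
    """
    pts = reference.grid_points()
    mapped = transform_points(pts, t)
    vals, inside = sample_trilinear(vol, mapped, background=background)
    out = Volume3D(vals.reshape(reference.shape), reference.spacing.copy(), reference.origin.copy())
    if return_inside:
        return out, inside.reshape(reference.shape)
    return out


# ---------------------------------------------------------------------------
# registration drivers
# ---------------------------------------------------------------------------


def _setup_common(R: sitk.ImageRegistrationMethod, bins: int, sampling: float, mask_img) -> None:
    R.SetMetricAsMattesMutualInformation(numberOfHistogramBins=bins)
    if sampling >= 1.0:
        R.SetMetricSamplingStrategy(R.NONE)
    else:
        R.SetMetricSamplingStrategy(R.REGULAR)
        R.SetMetricSamplingPercentage(sampling, seed=20120621)  # fixed seed: reproducible sampling
    R.SetInterpolator(sitk.sitkLinear)
    if mask_img is not None:
        R.SetMetricFixedMask(mask_img)


def register_linear(
    fixed: Volume3D,
    moving: Volume3D,
    mode: str = "rigid",
    bins: int = 32,
    max_iter: int = 200,
    mask: np.ndarray | None = None,
    sampling: float = 1.0,
    shrink_factors: tuple[int, ...] = (4, 2, 1),
    smoothing_sigmas: tuple[float, ...] = (2.0, 1.0, 0.0),
) -> tuple[AffineTransform, SimilarityReport]:
    """Rigid or affine registration maximizing mutual information, multi-resolution.

    Returns the transform mapping fixed-image world coordinates to
    moving-image world coordinates, and a :class:`SimilarityReport` with the
    Studholme NMI before and after.  The result is guaranteed not to have a
    lower masked NMI than the identity initialization; otherwise the identity
    is returned with ``converged=False``.
    """
    if mode not in ("rigid", "affine"):
        raise ValidationError(f"mode must be 'rigid' or 'affine', got {mode!r}")
    fixed_img = _to_sitk(fixed)
    moving_img = _to_sitk(moving)

    base = sitk.Euler3DTransform() if mode == "rigid" else sitk.AffineTransform(3)
    tx = sitk.CenteredTransformInitializer(
        fixed_img, moving_img, base, sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    R = sitk.ImageRegistrationMethod()
    _setup_common(R, bins, sampling, _mask_to_sitk(mask, fixed) if mask is not None else None)
    R.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-4,
        numberOfIterations=max_iter,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-8,
    )
    R.SetOptimizerScalesFromPhysicalShift()
    R.SetInitialTransform(tx, inPlace=True)
    R.SetShrinkFactorsPerLevel(list(shrink_factors))
    R.SetSmoothingSigmasPerLevel(list(smoothing_sigmas))
    R.Execute(fixed_img, moving_img)
    iterations = int(R.GetOptimizerIteration())

    M = _affine_from_sitk(tx)
    if mode == "rigid":
        M[:3, :3] = _orthonormalize(M[:3, :3])
    result = AffineTransform(M, rigid=(mode == "rigid"))

    bg = float(np.percentile(fixed.values, 1))
    moved0, inside0 = apply_transform(moving, AffineTransform.identity(), fixed, background=bg, return_inside=True)
    nmi_before = _masked_nmi(fixed, moved0, inside0, mask, bins)
    moved1, inside1 = apply_transform(moving, result, fixed, background=bg, return_inside=True)
    nmi_after = _masked_nmi(fixed, moved1, inside1, mask, bins)
    if nmi_after < nmi_before:
        return AffineTransform.identity(rigid=(mode == "rigid")), SimilarityReport(
            nmi_before, nmi_before, iterations, converged=False
        )
    return result, SimilarityReport(nmi_before, nmi_after, iterations, converged=True)


def _subdivide_axis(c: np.ndarray, axis: int) -> np.ndarray:
    """Exact dyadic refinement of cubic B-spline coefficients along one axis.

    A spline with coefficients c on knot spacing h is reproduced exactly on
    spacing h/2 by the subdivision stencil d_2k = (c_{k-1} + 6 c_k + c_{k+1})/8,
    d_{2k+1} = (c_k + c_{k+1})/2.  The returned array is laid out for a lattice
    whose first control point sits half a coarse spacing after the coarse one.
    """
    c = np.moveaxis(c, axis, 0)
    n = c.shape[0]
    m = n - 3
    fine = np.empty((2 * m + 3,) + c.shape[1:], dtype=c.dtype)
    for j in range(2 * m + 3):
        i = j + 1
        if i % 2 == 0:
            k = i // 2
            fine[j] = (c[k - 1] + 6.0 * c[k] + c[k + 1]) / 8.0
        else:
            k = (i - 1) // 2
            fine[j] = (c[k] + c[k + 1]) / 2.0
    return np.moveaxis(fine, 0, axis)


def refine_ffd(t: FFDTransform) -> FFDTransform:
    """Exactly re-express an FFD on a lattice with half the control spacing."""
    coeffs = t.coefficients
    for axis in range(3):
        coeffs = _subdivide_axis(coeffs, axis)
    return FFDTransform(
        t.lattice_origin + t.lattice_spacing / 2.0,
        t.lattice_spacing / 2.0,
        coeffs,
        affine=t.affine,
    )


def _ffd_to_sitk(t: FFDTransform) -> sitk.BSplineTransform:
    imgs = []
    for d in range(3):
        arr = np.ascontiguousarray(t.coefficients[..., d].transpose(2, 1, 0))
        img = sitk.GetImageFromArray(arr)
        img.SetSpacing(tuple(float(s) for s in t.lattice_spacing))
        img.SetOrigin(tuple(float(o) for o in t.lattice_origin))
        imgs.append(img)
    return sitk.BSplineTransform(imgs, 3)


def _ffd_from_sitk_bspline(tx, affine: AffineTransform | None) -> FFDTransform:
    fp = np.asarray(tx.GetFixedParameters(), dtype=float)
    size = fp[0:3].astype(int)
    origin = fp[3:6]
    spacing = fp[6:9]
    direction = fp[9:18].reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-9):
        raise ValidationError("non-identity B-spline lattice direction is not supported")
    params = np.asarray(tx.GetParameters(), dtype=float)
    nx, ny, nz = size
    coeffs = params.reshape(3, nz, ny, nx)  # ITK flattens component-major, x fastest
    coeffs = np.transpose(coeffs, (3, 2, 1, 0))
    return FFDTransform(origin, spacing, np.ascontiguousarray(coeffs), affine=affine)


def _entropies_from_hist(H: np.ndarray) -> float:
    total = H.sum()
    if total <= 0:
        raise DegenerateEntropyError("empty joint histogram")
    p = H / total
    ha = _entropy(p.sum(axis=1))
    hb = _entropy(p.sum(axis=0))
    hab = _entropy(p.ravel())
    if hab == 0.0:
        raise DegenerateEntropyError("joint entropy is zero")
    return (ha + hb) / hab


def _basis4(f: np.ndarray) -> np.ndarray:
    """(N, 4) cubic B-spline weights of the four contributing coefficients."""
    return np.stack(_bspline_weights(f), axis=1)


class _FFDLevel:
    """One resolution level of the coordinate-descent NMI optimizer.

    Holds the masked voxel sample, per-voxel B-spline basis tables, the joint
    histogram, and the per-control-point voxel index lists needed for
    incremental NMI updates when a single coefficient moves.
    """

    def __init__(self, fixed: Volume3D, moving: Volume3D, t: FFDTransform,
                 mask: np.ndarray | None, bins: int, sampling: float, bending_weight: float):
        self.t = t
        self.bins = bins
        self.bending_weight = bending_weight
        sel = np.ones(fixed.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
        idx = np.flatnonzero(sel.ravel())
        if sampling < 1.0 and idx.size:
            stride = max(1, int(round(1.0 / sampling)))
            idx = idx[::stride]
        if idx.size < 100:
            raise ValidationError("too few voxels in the registration mask")
        grid = fixed.grid_points()
        self.x = grid[idx]
        fvals = fixed.values.ravel()[idx]
        self.moving = moving
        self.affine = t.affine

        lo, hi = np.percentile(fvals, [1.0, 99.0])
        if hi <= lo:
            raise DegenerateEntropyError("constant fixed image within mask")
        self.f_edges = np.linspace(lo, hi, bins + 1)
        self.f_bin = np.clip(np.digitize(fvals, self.f_edges[1:-1]), 0, bins - 1)

        mlo, mhi = np.percentile(moving.values, [1.0, 99.0])
        if mhi <= mlo:
            raise DegenerateEntropyError("constant moving image")
        self.m_edges = np.linspace(mlo, mhi, bins + 1)

        # lattice cell and basis tables
        s = (self.x - t.lattice_origin) / t.lattice_spacing
        cell = np.floor(s).astype(int)
        shape = np.asarray(t.lattice_shape)
        cell = np.clip(cell, 1, shape - 3)
        self.cell = cell
        f = s - cell
        self.basis = [_basis4(f[:, d]) for d in range(3)]

        # per-control-point voxel lists with basis weights: coefficient g
        # affects voxels with cell in [g-2, g+1] per axis (g = cell - 1 + l);
        # near-zero weights at the support corners are pruned
        nx, ny, nz = t.lattice_shape
        pts = []
        vox = []
        wts = []
        all_vox = np.arange(len(idx))
        for lx in range(4):
            gx = cell[:, 0] - 1 + lx
            for ly in range(4):
                gy = cell[:, 1] - 1 + ly
                for lz in range(4):
                    gz = cell[:, 2] - 1 + lz
                    w = self.basis[0][:, lx] * self.basis[1][:, ly] * self.basis[2][:, lz]
                    keep = w >= 1e-3
                    pts.append(((gx * ny + gy) * nz + gz)[keep])
                    vox.append(all_vox[keep])
                    wts.append(w[keep])
        pts = np.concatenate(pts)
        vox = np.concatenate(vox)
        wts = np.concatenate(wts)
        order = np.argsort(pts, kind="stable")
        pts, self.vox_sorted, self.w_sorted = pts[order], vox[order], wts[order]
        self.point_slices = np.searchsorted(pts, np.arange(nx * ny * nz + 1))

        # displacement and moving-bin caches
        self.u = t.displacement(self.x)
        self.m_bin = np.empty(len(idx), dtype=np.int64)
        self.inside = np.empty(len(idx), dtype=bool)
        self._resample(np.arange(len(idx)), self.u, write=True)
        self.H = np.zeros((bins, bins))
        valid = self.inside
        np.add.at(self.H, (self.f_bin[valid], self.m_bin[valid]), 1.0)

    def _resample(self, vox: np.ndarray, u: np.ndarray, write: bool = False):
        pts = self.x[vox] + u
        if self.affine is not None:
            pts = self.affine.map_points(pts)
        vals, inside = sample_trilinear(self.moving, pts)
        b = np.clip(np.digitize(vals, self.m_edges[1:-1]), 0, self.bins - 1)
        if write:
            self.m_bin[vox] = b
            self.inside[vox] = inside
        return b, inside

    def nmi(self) -> float:
        return _entropies_from_hist(self.H)

    def resync(self) -> None:
        """Re-evaluate the caches from the exact transform.

        Trial updates ignore support entries with pruned (near-zero) basis
        weights, so the cached displacement drifts slightly from the true
        B-spline; resyncing between sweeps keeps the optimized objective tied
        to the transform actually returned.
        """
        self.u = self.t.displacement(self.x)
        self._resample(np.arange(len(self.x)), self.u, write=True)
        self.H[:] = 0.0
        valid = self.inside
        np.add.at(self.H, (self.f_bin[valid], self.m_bin[valid]), 1.0)

    def _bending_local(self, coeffs: np.ndarray, g: tuple[int, int, int], comp: int) -> float:
        """Axis-wise squared second differences (slope units) touching point g."""
        total = 0.0
        shape = coeffs.shape[:3]
        for axis in range(3):
            h = self.t.lattice_spacing[axis]
            for off in (-1, 0, 1):
                k = g[axis] + off
                if 1 <= k <= shape[axis] - 2:
                    i0 = list(g)
                    i0[axis] = k - 1
                    i1 = list(g)
                    i1[axis] = k
                    i2 = list(g)
                    i2[axis] = k + 1
                    d2 = coeffs[tuple(i0)][comp] - 2.0 * coeffs[tuple(i1)][comp] + coeffs[tuple(i2)][comp]
                    total += (d2 / h) ** 2
        return total

    def sweep(self, active_points: np.ndarray, step: float, tol: float) -> int:
        """One Gauss-Seidel pass over active control points; returns accepted moves."""
        coeffs = self.t.coefficients
        nx, ny, nz = self.t.lattice_shape
        score = self.nmi()
        accepted = 0
        nb = self.bins
        for p in active_points:
            g = (p // (ny * nz), (p // nz) % ny, p % nz)
            sl = slice(self.point_slices[p], self.point_slices[p + 1])
            vox = self.vox_sorted[sl]
            if vox.size == 0:
                continue
            w = self.w_sorted[sl]
            fb = self.f_bin[vox]
            for comp in range(3):
                old_b = self.m_bin[vox]
                old_in = self.inside[vox]
                old_flat = (fb * nb + old_b)[old_in]
                bend0 = self._bending_local(coeffs, g, comp)
                for sign in (1.0, -1.0):
                    delta = sign * step
                    u_new = self.u[vox].copy()
                    u_new[:, comp] += delta * w
                    new_b, new_in = self._resample(vox, u_new)
                    new_flat = (fb * nb + new_b)[new_in]
                    dH = (
                        np.bincount(new_flat, minlength=nb * nb).astype(np.float64)
                        - np.bincount(old_flat, minlength=nb * nb)
                    ).reshape(nb, nb)
                    self.H += dH
                    try:
                        nmi_new = self.nmi()
                    except DegenerateEntropyError:
                        nmi_new = -np.inf
                    coeffs[g][comp] += delta
                    bend1 = self._bending_local(coeffs, g, comp)
                    gain = (nmi_new - score) - self.bending_weight * (bend1 - bend0)
                    if gain > tol:  # accept first improvement
                        self.u[vox] = u_new
                        self.m_bin[vox] = new_b
                        self.inside[vox] = new_in
                        score = nmi_new
                        accepted += 1
                        break
                    coeffs[g][comp] -= delta
                    self.H -= dH
        return accepted


def _downsample(vol: Volume3D, factor: int) -> Volume3D:
    if factor <= 1:
        return vol
    from scipy.ndimage import gaussian_filter

    sm = gaussian_filter(vol.values, factor / 2.0)
    return Volume3D(sm[::factor, ::factor, ::factor], vol.spacing * factor, vol.origin.copy())


def _smooth(vol: Volume3D, sigma_vox: float) -> Volume3D:
    if sigma_vox <= 0:
        return vol
    from scipy.ndimage import gaussian_filter

    return vol.copy_with(gaussian_filter(vol.values, sigma_vox))


def register_ffd(
    fixed: Volume3D,
    moving: Volume3D,
    init: AffineTransform | None = None,
    lattice_spacing: float = 18.0,
    bins: int = 32,
    max_iter: int = 12,
    levels: int = 3,
    mask: np.ndarray | None = None,
    sampling: float | None = None,
    bending_weight: float = 5e-4,
    initial_step_mm: float | None = None,
    min_step_mm: float = 0.1,
    tol: float = 1e-6,
    level_transforms: list | None = None,
) -> tuple[FFDTransform, SimilarityReport]:
    """Free-form deformation registration maximizing normalized mutual information.

    Coarse-to-fine over ``levels``: the control lattice starts at
    ``lattice_spacing * 2**(levels-1)`` mm and is refined by exact dyadic
    B-spline subdivision, while the fixed image is processed on a matching
    pyramid.  Within a level, control-point displacements are optimized by a
    deterministic Gauss-Seidel coordinate search with step halving: each
    candidate move is scored by the change in Studholme NMI (updated
    incrementally on the joint histogram over the masked voxels) minus a
    bending-energy penalty (axis-wise squared second differences of the
    coefficients, weight ``bending_weight``).  Moves that do not improve the
    score are rejected, so deformation components the images cannot constrain
    (e.g. motion along homogeneous intensity bands) are never introduced.

    ``max_iter`` caps the sweeps per level; convergence when the step falls
    below ``min_step_mm``.  ``sampling`` (0..1] thins the masked voxels used
    for the histogram (deterministic stride; default keeps at most ~40k).
    The optional affine ``init`` is composed as ``T(x) = A(x + u(x))``.  The
    returned transform never has a lower masked NMI than ``init`` alone.
    """
    if levels < 1:
        raise ValidationError("levels must be >= 1")
    if lattice_spacing < 2.0 * float(np.max(fixed.spacing)):
        raise ValidationError(
            f"lattice spacing {lattice_spacing} mm is below 2 voxels "
            f"({2.0 * float(np.max(fixed.spacing))} mm) of the fixed image"
        )

    # coarsest lattice covering the fixed domain with one control point margin
    h0 = lattice_spacing * 2 ** (levels - 1)
    extent = (np.asarray(fixed.shape) - 1) * fixed.spacing
    n_pts = np.ceil(extent / h0).astype(int) + 4
    origin0 = fixed.origin - h0
    t = FFDTransform(origin0, np.full(3, h0), np.zeros(tuple(n_pts) + (3,)), affine=init)

    iterations = 0
    converged = True
    candidates: list[FFDTransform] = []
    for level in range(levels):
        shrink = 2 ** (levels - 1 - level)
        if level > 0:
            t = refine_ffd(t)
        fixed_l = _downsample(fixed, shrink)
        moving_l = _smooth(moving, shrink / 2.0) if shrink > 1 else moving
        mask_l = None
        if mask is not None:
            mask_l = np.asarray(mask, dtype=bool)[::shrink, ::shrink, ::shrink]
        n_masked = int(mask_l.sum()) if mask_l is not None else int(np.prod(fixed_l.shape))
        if n_masked < 48 * bins:
            # too few voxels for a stable joint histogram at this pyramid
            # level; optimizing here would only fit sampling noise
            continue
        samp = sampling if sampling is not None else min(1.0, 40000.0 / max(n_masked, 1))
        state = _FFDLevel(fixed_l, moving_l, t, mask_l, bins, samp, bending_weight)

        # control points with enough voxel support
        counts = np.diff(state.point_slices)
        active = np.flatnonzero(counts >= 16)
        step = initial_step_mm if initial_step_mm is not None else 1.5 * float(np.max(fixed.spacing))
        sweeps = 0
        while step >= min_step_mm and sweeps < max_iter:
            accepted = state.sweep(active, step, tol)
            sweeps += 1
            if accepted == 0:
                step /= 2.0
            else:
                state.resync()
        iterations += sweeps
        if step >= min_step_mm:
            converged = False
        snapshot = FFDTransform(
            t.lattice_origin.copy(), t.lattice_spacing.copy(), t.coefficients.copy(), affine=init
        )
        candidates.append(snapshot)
        if level_transforms is not None:
            level_transforms.append(snapshot)

    bg = float(np.percentile(fixed.values, 1))

    def full_nmi(transform) -> float:
        moved, inside = apply_transform(moving, transform, fixed, background=bg, return_inside=True)
        return _masked_nmi(fixed, moved, inside, mask, bins)

    init_t = init if init is not None else AffineTransform.identity()
    nmi_before = full_nmi(init_t)
    # the guarantee is enforced against the full-resolution masked NMI: keep
    # the best transform across the refinement hierarchy, falling back to the
    # (zero-displacement) initialization if no level improved on it
    zero = FFDTransform(t.lattice_origin, t.lattice_spacing, np.zeros_like(t.coefficients), affine=init)
    best, best_nmi, improved = zero, nmi_before, False
    for cand in candidates:
        cand_nmi = full_nmi(cand)
        if cand_nmi > best_nmi:
            best, best_nmi, improved = cand, cand_nmi, True
    return best, SimilarityReport(nmi_before, best_nmi, iterations, converged=converged and improved)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def affine_to_json(t: AffineTransform) -> str:
    import json

    return json.dumps({"matrix": t.matrix.ravel().tolist(), "rigid": t.rigid})


def affine_from_json(text: str) -> AffineTransform:
    import json

    d = json.loads(text)
    return AffineTransform(np.asarray(d["matrix"], dtype=float).reshape(4, 4), rigid=d["rigid"])


def save_ffd(t: FFDTransform, nifti_path, header_path) -> None:
    """Write an FFD as a 3-component NIfTI coefficient image plus a JSON lattice header."""
    import json

    from .image import write_vector_field

    write_vector_field(t.coefficients, t.lattice_spacing, t.lattice_origin, nifti_path)
    header = {
        "lattice_origin": t.lattice_origin.tolist(),
        "lattice_spacing": t.lattice_spacing.tolist(),
        "affine": None if t.affine is None else {
            "matrix": t.affine.matrix.ravel().tolist(), "rigid": t.affine.rigid},
    }
    with open(header_path, "w") as fh:
        json.dump(header, fh, indent=2)


def load_ffd(nifti_path, header_path) -> FFDTransform:
    import json

    from .image import read_vector_field

    coeffs, _, _ = read_vector_field(nifti_path)
    with open(header_path) as fh:
        header = json.load(fh)
    affine = None
    if header["affine"] is not None:
        affine = AffineTransform(
            np.asarray(header["affine"]["matrix"], dtype=float).reshape(4, 4),
            rigid=header["affine"]["rigid"],
        )
    return FFDTransform(header["lattice_origin"], header["lattice_spacing"], coeffs, affine=affine)
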