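"""Axis-aligned volumetric data model, interpolation, and NIfTI-1 I/O.

Conventions
-----------
* Arrays are indexed ``values[i, j, k]`` with axis 0 = world x, axis 1 = world
  y, axis 2 = world z.
* Voxel indices are 0-based.  The world coordinate (mm) of voxel ``(i, j, k)``
  is ``origin + (i, j, k) * spacing`` — the geometry is axis-aligned; rotated
  or sheared NIfTI affines are rejected on read.
* All internal computation is double precision; image files are written as
  float32 and label files as uint8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from .exceptions import FormatError, ValidationError

LABEL_BACKGROUND = 0
LABEL_LV_BLOOD = 1
LABEL_LV_WALL = 2
LABEL_RV_BLOOD = 3
VALID_LABELS = (LABEL_BACKGROUND, LABEL_LV_BLOOD, LABEL_LV_WALL, LABEL_RV_BLOOD)


def _as_triple(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size != 3:
        raise ValidationError(f"{name} must have exactly 3 components, got {arr.size}")
    return arr


@dataclass
class Volume3D:
    """A 3D scalar field with anisotropic voxel spacing and a world origin.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar intensities in arbitrary units.
    spacing : sequence of 3 floats
        Per-axis voxel size in mm; all strictly positive.
    origin : sequence of 3 floats
        World position (mm) of the *center* of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValidationError(f"values must be 3D, got ndim={self.values.ndim}")
        if min(self.values.shape) < 2:
            raise ValidationError(f"grid dimensions must be >= 2 along every axis, got {self.values.shape}")
        self.spacing = _as_triple(self.spacing, "spacing")
        if not np.all(self.spacing > 0):
            raise ValidationError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "Volume3D | LabelVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def grid_points(self) -> np.ndarray:
        """World coordinates (mm) of all voxel centers, shape (N, 3)."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.origin + idx * self.spacing

    def copy_with(self, values: np.ndarray) -> "Volume3D":
        return Volume3D(values, self.spacing.copy(), self.origin.copy())


@dataclass
class LabelVolume:
    """Categorical volume with codes 0=background, 1=LV blood pool, 2=LV wall, 3=RV blood pool."""

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError(f"labels must be 3D, got ndim={self.labels.ndim}")
        if min(self.labels.shape) < 2:
            raise ValidationError(f"grid dimensions must be >= 2 along every axis, got {self.labels.shape}")
        if not np.isin(self.labels, VALID_LABELS).all():
            bad = np.setdiff1d(np.unique(self.labels), VALID_LABELS)
            raise ValidationError(f"label codes restricted to {VALID_LABELS}, found {bad}")
        self.labels = self.labels.astype(np.uint8)
        self.spacing = _as_triple(self.spacing, "spacing")
        if not np.all(self.spacing > 0):
            raise ValidationError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    def as_volume(self) -> Volume3D:
        return Volume3D(self.labels.astype(np.float64), self.spacing.copy(), self.origin.copy())


def world_from_index(vol: Volume3D | LabelVolume, index) -> np.ndarray:
    """World coordinate (mm) of a voxel index; raises IndexError out of bounds."""
    idx = np.asarray(index)
    shape = np.asarray(vol.shape)
    if idx.shape[-1] != 3:
        raise ValidationError("index must have 3 components")
    if np.any(idx < 0) or np.any(idx >= shape):
        raise IndexError(f"index {index} outside grid of shape {vol.shape}")
    return vol.origin + idx * vol.spacing


def index_from_world(vol: Volume3D | LabelVolume, point) -> np.ndarray:
    """Continuous voxel coordinate of a world point (inverse of world_from_index)."""
    return (np.asarray(point, dtype=float) - vol.origin) / vol.spacing


def sample_trilinear(
    vol: Volume3D, points, background: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear interpolation of a volume at world points.

    Points outside the voxel-center hull return ``background`` and are flagged
    out-of-domain rather than raising.

    Parameters
    ----------
    points : ndarray, shape (N, 3) or (3,)
        World coordinates in mm.

    Returns
    -------
    values : ndarray, shape (N,)
    inside : ndarray of bool, shape (N,)
        True where the point lies within the grid's voxel-center hull.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    coords = (pts - vol.origin) / vol.spacing  # continuous index coordinates
    upper = np.asarray(vol.shape) - 1
    inside = np.all((coords >= 0.0) & (coords <= upper), axis=1)
    out = map_coordinates(vol.values, coords.T, order=1, mode="constant", cval=background)
    out = np.where(inside, out, background)
    return out, inside


# ---------------------------------------------------------------------------
# NIfTI-1 I/O
# ---------------------------------------------------------------------------

def _grid_from_affine(affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lin = affine[:3, :3]
    diag = np.diag(lin)
    off = lin - np.diag(diag)
    scale = max(np.abs(diag).max(), 1.0)
    if np.abs(off).max() > 1e-4 * scale:
        raise FormatError(
            "affine (srow/qform): rotation or shear components are not supported; "
            "only axis-aligned volumes can be read"
        )
    if np.any(diag <= 0):
        raise FormatError(
            f"affine (pixdim/srow): spacings must be strictly positive, got diagonal {diag}"
        )
    return diag.copy(), affine[:3, 3].copy()


def _load_nifti(path):
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except FormatError:
        raise
    except Exception as exc:  # nibabel raises a zoo of errors on malformed files
        raise FormatError(f"could not read {path} as NIfTI-1: {exc}") from exc
    return img, data

def _squeeze3d(data: np.ndarray, path) -> np.ndarray:
    if data.ndim > 3:
        if all(s == 1 for s in data.shape[3:]):
            data = data.reshape(data.shape[:3])
        else:
            raise FormatError(f"dim: expected a 3D volume in {path}, got shape {data.shape}")
    if data.ndim != 3:
        raise FormatError(f"dim: expected a 3D volume in {path}, got shape {data.shape}")
    return data


def read_volume(path) -> Volume3D:
    """Read an axis-aligned 3D NIfTI-1 volume (.nii / .nii.gz)."""
    img, data = _load_nifti(path)
    spacing, origin = _grid_from_affine(img.affine)
    return Volume3D(_squeeze3d(data, path).astype(np.float64), spacing, origin)


def write_volume(vol: Volume3D, path) -> None:
    """Write a volume as float32 NIfTI-1 with a diagonal affine."""
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vol.spacing)
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), affine), str(path))


def read_labels(path) -> LabelVolume:
    img, data = _load_nifti(path)
    spacing, origin = _grid_from_affine(img.affine)
    data = _squeeze3d(data, path)
    if not np.isin(data, VALID_LABELS).all():
        raise FormatError(f"datatype: label file {path} contains codes outside {VALID_LABELS}")
    return LabelVolume(data.astype(np.uint8), spacing, origin)


def write_labels(labels: LabelVolume, path) -> None:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(labels.spacing)
    affine[:3, 3] = labels.origin
    nib.save(nib.Nifti1Image(labels.labels.astype(np.uint8), affine), str(path))


def read_vector_field(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a 3-component vector image; returns (field (nx,ny,nz,3), spacing, origin)."""
    img, data = _load_nifti(path)
    spacing, origin = _grid_from_affine(img.affine)
    if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector convention (x,y,z,1,3)
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise FormatError(f"dim: expected a 3-component vector image in {path}, got {data.shape}")
    return data.astype(np.float64), spacing, origin


def write_vector_field(field: np.ndarray, spacing, origin, path) -> None:
    field = np.asarray(field, dtype=np.float32)
    if field.ndim != 4 or field.shape[-1] != 3:
        raise ValidationError(f"vector field must have shape (nx, ny, nz, 3), got {field.shape}")
    affine = np.eye(4)
    affine[:3, :3] = np.diag(np.asarray(spacing, dtype=float))
    affine[:3, 3] = np.asarray(origin, dtype=float)
    nib.save(nib.Nifti1Image(field[:, :, :, np.newaxis, :], affine), str(path))
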