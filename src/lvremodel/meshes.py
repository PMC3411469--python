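"""Surface reconstruction, wall thickness, and the local remodeling statistic.

Local ventricular remodeling at a vertex is the percentage change, under the
longitudinal transform, of the mean separation between that vertex and its
1-ring neighbors:

    d0(v) = mean_{u in N(v)} ||x_v - x_u||
    d1(v) = the same after mapping both endpoints through the transform
    remodeling(v) = 100 * (d1 - d0) / d0

The statistic depends only on mesh geometry and the transform — never on the
infarct segmentation — so it is independent of infarct size by construction.
Rigid motion composed into the transform contributes exactly zero; a global
similarity with ratio s yields exactly 100*(s-1) everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.measure import marching_cubes

from .exceptions import ValidationError
from .image import LABEL_LV_BLOOD, LABEL_LV_WALL, LabelVolume
from .registration import transform_points

REGION_REMOTE = 0
REGION_INFARCT = 1
REGION_UNDEFINED = -1
REGION_NAMES = {REGION_REMOTE: "remote", REGION_INFARCT: "infarct", REGION_UNDEFINED: "undefined"}


@dataclass
class SurfaceMesh:
    """Triangulated surface in world mm with named per-vertex scalar channels."""

    vertices: np.ndarray  # (V, 3) mm
    faces: np.ndarray  # (F, 3) int
    attributes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValidationError("face indices out of vertex range")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @property
    def euler_characteristic(self) -> int:
        tm = self.to_trimesh()
        return int(len(tm.vertices) - len(tm.edges_unique) + len(tm.faces))

    @property
    def volume_ml(self) -> float:
        """Enclosed volume in ml (meaningful for closed surfaces)."""
        return float(abs(self.to_trimesh().volume) / 1000.0)

    def with_vertices(self, vertices: np.ndarray) -> "SurfaceMesh":
        return SurfaceMesh(vertices, self.faces.copy(), dict(self.attributes))


def _cleanup(vertices: np.ndarray, faces: np.ndarray) -> SurfaceMesh:
    tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=True, validate=True)
    # keep the largest connected component
    parts = tm.split(only_watertight=False)
    if len(parts) > 1:
        tm = max(parts, key=lambda p: len(p.faces))
    tm.update_faces(tm.nondegenerate_faces())
    tm.remove_unreferenced_vertices()
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def extract_surfaces(
    labels: LabelVolume,
    smooth_sigma_vox: float = 1.0,
    step_size: int = 1,
) -> tuple[SurfaceMesh, SurfaceMesh]:
    """Endocardial and epicardial surfaces from an LV segmentation.

    The endocardium is the 0.5 iso-surface of the (smoothed) LV blood-pool
    indicator; the epicardium that of the blood-pool+wall indicator.
    ``step_size`` coarsens the marching-cubes grid (mesh decimation).
    """
    blood = labels.mask(LABEL_LV_BLOOD)
    wall = labels.mask(LABEL_LV_WALL)
    if not blood.any():
        raise ValidationError("LV blood-pool class is empty")
    if not wall.any():
        raise ValidationError("LV wall class is empty")

    def _extract(indicator: np.ndarray) -> SurfaceMesh:
        f = indicator.astype(np.float64)
        if smooth_sigma_vox > 0:
            f = gaussian_filter(f, smooth_sigma_vox)
        f = np.pad(f, 1, mode="constant")  # guarantee closed surfaces at the grid edge
        verts, faces, _, _ = marching_cubes(
            f, level=0.5, spacing=tuple(labels.spacing), step_size=step_size
        )
        verts = verts - labels.spacing + labels.origin  # undo padding offset
        return _cleanup(verts, faces)

    endo = _extract(blood)
    epi = _extract(blood | wall)
    return endo, epi


def wall_thickness(epi: SurfaceMesh, endo: SurfaceMesh) -> np.ndarray:
    """Wall thickness (mm) at each epicardial vertex: distance to the nearest endocardial vertex."""
    if len(endo.vertices) == 0:
        raise ValidationError("endocardial mesh is empty")
    if len(epi.vertices) == 0:
        raise ValidationError("epicardial mesh is empty")
    dist, _ = cKDTree(endo.vertices).query(epi.vertices)
    return np.asarray(dist, dtype=float)


def neighbor_graph(mesh: SurfaceMesh) -> list[np.ndarray]:
    """1-ring vertex adjacency from shared triangle edges; symmetric by construction."""
    n = len(mesh.vertices)
    edges = np.vstack(
        [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
    )
    both = np.vstack([edges, edges[:, ::-1]])
    both = np.unique(both, axis=0)
    both = both[both[:, 0] != both[:, 1]]
    nbrs: list[np.ndarray] = [np.empty(0, dtype=np.int64) for _ in range(n)]
    split_at = np.searchsorted(both[:, 0], np.arange(n + 1))
    for v in range(n):
        nbrs[v] = both[split_at[v] : split_at[v + 1], 1]
    if any(len(a) == 0 for a in nbrs):
        warnings.warn("isolated vertices present; their remodeling is undefined")
    return nbrs


def _mean_neighbor_separation(vertices: np.ndarray, edge_v: np.ndarray, edge_u: np.ndarray, n: int) -> np.ndarray:
    d = np.linalg.norm(vertices[edge_v] - vertices[edge_u], axis=1)
    sums = np.zeros(n)
    counts = np.zeros(n)
    np.add.at(sums, edge_v, d)
    np.add.at(counts, edge_v, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
    mean[counts == 0] = np.nan
    return mean


def local_remodeling(mesh: SurfaceMesh, transform) -> np.ndarray:
    """Per-vertex local remodeling (%): change in mean 1-ring neighbor separation under the transform.

    ``transform`` may be an :class:`~lvremodel.registration.AffineTransform`,
    an :class:`~lvremodel.registration.FFDTransform`, or any callable mapping
    (N, 3) baseline world points to follow-up world points.  Vertices with no
    neighbors are returned as NaN.
    """
    nbrs = neighbor_graph(mesh)
    edge_v = np.concatenate([np.full(len(a), v) for v, a in enumerate(nbrs)]) if nbrs else np.empty(0, int)
    edge_u = np.concatenate(nbrs) if nbrs else np.empty(0, int)
    n = len(mesh.vertices)
    v0 = mesh.vertices
    v1 = transform_points(v0, transform)
    d0 = _mean_neighbor_separation(v0, edge_v, edge_u, n)
    d1 = _mean_neighbor_separation(v1, edge_v, edge_u, n)
    with np.errstate(invalid="ignore", divide="ignore"):
        return 100.0 * (d1 - d0) / d0


@dataclass
class RemodelingMap:
    """Per-epicardial-vertex scalars: thickness (mm), transmural extent, remodeling (%), region."""

    mesh: SurfaceMesh
    thickness_base: np.ndarray
    thickness_follow: np.ndarray
    transmural_extent: np.ndarray
    remodeling_pct: np.ndarray
    region: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.mesh.vertices)
        for name in ("thickness_base", "thickness_follow", "transmural_extent", "remodeling_pct"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have one value per epicardial vertex")
            setattr(self, name, arr)

    def channels(self) -> dict[str, np.ndarray]:
        out = {
            "thickness_base": self.thickness_base,
            "thickness_follow": self.thickness_follow,
            "transmural_extent": self.transmural_extent,
            "remodeling_pct": self.remodeling_pct,
        }
        if self.region is not None:
            out["region"] = self.region.astype(float)
        return out

    def region_mean(self, region_code: int, channel: str = "remodeling_pct") -> float:
        if self.region is None:
            raise ValidationError("regions not assigned; call assign_regions first")
        vals = self.channels()[channel][self.region == region_code]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else float("nan")


def assign_regions(rmap: RemodelingMap, extent_threshold: float = 0.0) -> RemodelingMap:
    """Label vertices infarct (extent > threshold), remote (0..threshold), or undefined (NaN)."""
    extent = rmap.transmural_extent
    region = np.full(len(extent), REGION_REMOTE, dtype=np.int64)
    region[extent > extent_threshold] = REGION_INFARCT
    region[~np.isfinite(extent)] = REGION_UNDEFINED
    rmap.region = region
    return rmap


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def write_vtk(mesh: SurfaceMesh, path, channels: dict[str, np.ndarray] | None = None) -> None:
    """Write legacy ASCII VTK polydata with per-vertex scalar channels."""
    channels = channels if channels is not None else mesh.attributes
    lines = [
        "# vtk DataFile Version 3.0",
        "lvremodel surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(mesh.vertices)} float",
    ]
    lines += [" ".join(f"{c:.6f}" for c in v) for v in mesh.vertices]
    lines.append(f"POLYGONS {len(mesh.faces)} {4 * len(mesh.faces)}")
    lines += ["3 " + " ".join(str(int(i)) for i in f) for f in mesh.faces]
    if channels:
        lines.append(f"POINT_DATA {len(mesh.vertices)}")
        for name, values in channels.items():
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{float(v):.6f}" for v in np.asarray(values, dtype=float)]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_ply(mesh: SurfaceMesh, path) -> None:
    mesh.to_trimesh().export(str(path), file_type="ply", encoding="ascii")
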