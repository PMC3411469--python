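"""Synthetic left-ventricle phantoms with known ground truth.

The generator emulates the statistical structure a post-infarction CMR study
assumes: a truncated-ellipsoid myocardial shell between blood pool and
background (plus a simple lateral RV pool), distinct class mean intensities
with additive Gaussian noise, a sectoral infarct of configurable transmural
fraction growing from the endocardium outward, an optional low-signal
microvascular-obstruction (MVO) core, and a follow-up volume produced by a
known smooth radial expansion of the infarct sector.  Every generator is
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ValidationError
from .image import (
    LABEL_BACKGROUND,
    LABEL_LV_BLOOD,
    LABEL_LV_WALL,
    LABEL_RV_BLOOD,
    LabelVolume,
    Volume3D,
    read_labels,
    read_vector_field,
    read_volume,
    sample_trilinear,
    write_labels,
    write_vector_field,
    write_volume,
)
from .segmentation import ProbabilisticAtlas


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    Geometry: the LV long axis is world z; the shell lies between two
    concentric ellipsoids truncated by a basal plane ``z <= center_z + base_cut_mm``.
    The infarct sector is defined in cylindrical coordinates about the long
    axis: an angular window around ``sector_center_deg`` and a long-axis slab
    ``sector_z_mm`` (offsets from the LV center).
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.8, 1.8, 2.4)
    endo_semi_axes: tuple[float, float, float] = (22.0, 22.0, 40.0)
    epi_semi_axes: tuple[float, float, float] = (30.0, 30.0, 48.0)
    base_cut_mm: float = 24.0  # basal truncation plane, offset from center along +z

    # structural ("cine") class mean intensities and noise
    mean_background: float = 20.0
    mean_lv_blood: float = 140.0
    mean_lv_wall: float = 80.0
    mean_rv_blood: float = 130.0
    noise_sigma: float = 12.0  # 20% of wall/blood contrast

    # infarct sector
    sector_center_deg: float = 0.0
    sector_width_deg: float = 60.0
    sector_taper_deg: float = 15.0
    sector_z_mm: tuple[float, float] = (-30.0, 10.0)
    sector_z_taper_mm: float = 8.0
    transmural_fraction: float = 0.6

    # LGE contrast model
    lge_remote_mean: float = 60.0
    lge_enhancing_mean: float = 160.0
    lge_blood_mean: float = 110.0
    lge_sigma: float = 20.0  # 20% of enhancement contrast

    # early-enhancement / MVO model
    mvo: bool = False
    mvo_core_fraction: float = 0.5
    early_remote_mean: float = 60.0
    early_enhancing_mean: float = 110.0
    early_mvo_mean: float = 20.0
    early_blood_mean: float = 100.0
    early_sigma: float = 10.0

    # longitudinal expansion
    expansion_factor: float = 1.0  # s; radial expansion within the sector

    seed: int = 0

    def __post_init__(self) -> None:
        endo = np.asarray(self.endo_semi_axes, dtype=float)
        epi = np.asarray(self.epi_semi_axes, dtype=float)
        if not np.all(epi > endo):
            raise ValidationError(
                f"epi semi-axes {tuple(epi)} must strictly exceed endo semi-axes {tuple(endo)}"
            )
        if not (0.0 <= self.transmural_fraction <= 1.0):
            raise ValidationError(f"transmural fraction must lie in [0,1], got {self.transmural_fraction}")
        if not (0.0 <= self.mvo_core_fraction <= 1.0):
            raise ValidationError(f"MVO core fraction must lie in [0,1], got {self.mvo_core_fraction}")
        for name in ("noise_sigma", "lge_sigma", "early_sigma"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.expansion_factor < 0:
            raise ValidationError(f"expansion factor must be >= 0, got {self.expansion_factor}")
        if self.sector_z_mm[1] <= self.sector_z_mm[0]:
            raise ValidationError("sector z extent must be an increasing interval")

    @property
    def center_mm(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        for key in ("shape", "spacing", "endo_semi_axes", "epi_semi_axes", "sector_z_mm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Oracle state for one phantom: labels, masks, true deformation, sector geometry."""

    labels: LabelVolume
    infarct_mask: np.ndarray
    mvo_mask: np.ndarray
    spec: PhantomSpec
    displacement_field: np.ndarray | None = None  # (nx,ny,nz,3) mm, baseline -> follow-up
    transmural_t: np.ndarray | None = None  # per-voxel radial position in wall, [0,1]
    clean_values: np.ndarray = field(default=None, repr=False)  # noise-free cine intensities

    def wall_mask(self) -> np.ndarray:
        return self.labels.mask(LABEL_LV_WALL)

    def in_sector(self, points: np.ndarray, angle_margin_deg: float = 0.0, z_margin_mm: float = 0.0) -> np.ndarray:
        """True where world points fall inside the infarct sector (optionally shrunk by margins)."""
        pts = np.atleast_2d(points)
        c = self.spec.center_mm
        theta = np.degrees(np.arctan2(pts[:, 1] - c[1], pts[:, 0] - c[0]))
        dtheta = np.abs((theta - self.spec.sector_center_deg + 180.0) % 360.0 - 180.0)
        z = pts[:, 2] - c[2]
        zlo, zhi = self.spec.sector_z_mm
        return (
            (dtheta <= self.spec.sector_width_deg / 2.0 - angle_margin_deg)
            & (z >= zlo + z_margin_mm)
            & (z <= zhi - z_margin_mm)
        )

    def true_transmural(self, points: np.ndarray, angle_margin_deg: float = 0.0, z_margin_mm: float = 0.0) -> np.ndarray:
        """Generator transmural fraction at each world point: f inside the sector, 0 outside."""
        inside = self.in_sector(points, angle_margin_deg, z_margin_mm)
        return np.where(inside, self.spec.transmural_fraction, 0.0)


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _grid_coords(spec: PhantomSpec):
    sp = np.asarray(spec.spacing)
    axes = [np.arange(n) * s for n, s in zip(spec.shape, sp)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    c = spec.center_mm
    return X - c[0], Y - c[1], Z - c[2]


def _ellipsoid_q(dx, dy, dz, semi_axes):
    a, b, c = semi_axes
    return np.sqrt((dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2)


def _region_masks(spec: PhantomSpec):
    """Per-voxel masks and the endo->epi radial coordinate t in [0, 1] on the wall."""
    dx, dy, dz = _grid_coords(spec)
    q_en = _ellipsoid_q(dx, dy, dz, spec.endo_semi_axes)
    q_ep = _ellipsoid_q(dx, dy, dz, spec.epi_semi_axes)
    below_base = dz <= spec.base_cut_mm
    blood = (q_en < 1.0) & below_base
    wall = (q_en >= 1.0) & (q_ep <= 1.0) & below_base

    # radial position across the wall along the ray from the LV center
    r = np.sqrt(dx**2 + dy**2 + dz**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_en = r / q_en
        r_ep = r / q_ep
        t = (r - r_en) / (r_ep - r_en)
    t = np.clip(np.where(wall, t, 0.0), 0.0, 1.0)

    # simple RV blood pool attached laterally on the -x side
    a_ep = spec.epi_semi_axes[0]
    rv_center = np.array([-(a_ep + 8.0), 0.0, -4.0])
    q_rv = _ellipsoid_q(dx - rv_center[0], dy - rv_center[1], dz - rv_center[2], (14.0, 20.0, 32.0))
    rv = (q_rv < 1.0) & (q_ep > 1.0) & below_base

    return blood, wall, rv, t


def _sector_masks(spec: PhantomSpec, wall: np.ndarray, t: np.ndarray):
    dx, dy, dz = _grid_coords(spec)
    theta = np.degrees(np.arctan2(dy, dx))
    dtheta = np.abs((theta - spec.sector_center_deg + 180.0) % 360.0 - 180.0)
    zlo, zhi = spec.sector_z_mm
    sector = (dtheta <= spec.sector_width_deg / 2.0) & (dz >= zlo) & (dz <= zhi)
    infarct = wall & sector & (t <= spec.transmural_fraction)
    if spec.transmural_fraction == 0.0:
        infarct &= False

    mvo = np.zeros_like(infarct)
    if spec.mvo and spec.mvo_core_fraction > 0 and infarct.any():
        # innermost core: threshold the radial coordinate at the quantile that
        # captures the requested fraction of infarct voxels
        tq = np.quantile(t[infarct], spec.mvo_core_fraction)
        mvo = infarct & (t <= tq)
    return infarct, mvo


def shell_volume_ml(spec: PhantomSpec) -> float:
    """Closed-form volume (ml) of the truncated ellipsoid shell between endo and epi.

    For an ellipsoid with semi-axes (a, b, c), the volume below the plane
    z = h (|h| <= c) is pi*a*b*(h - h^3/(3 c^2) + 2c/3).
    """

    def cap_volume(semi, h):
        a, b, c = semi
        h = min(h, c)
        return np.pi * a * b * (h - h**3 / (3 * c**2) + 2 * c / 3)

    v_ep = cap_volume(spec.epi_semi_axes, spec.base_cut_mm)
    v_en = cap_volume(spec.endo_semi_axes, spec.base_cut_mm)
    return float(v_ep - v_en) / 1000.0


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _class_image(spec: PhantomSpec, labels: np.ndarray, means: dict[int, float]) -> np.ndarray:
    out = np.full(spec.shape, means[LABEL_BACKGROUND], dtype=np.float64)
    for code, mean in means.items():
        if code != LABEL_BACKGROUND:
            out[labels == code] = mean
    return out


def make_lv_phantom(spec: PhantomSpec) -> tuple[Volume3D, GroundTruth]:
    """Generate the baseline structural ("cine end-diastolic") volume and its ground truth."""
    blood, wall, rv, t = _region_masks(spec)
    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[blood] = LABEL_LV_BLOOD
    labels[wall] = LABEL_LV_WALL
    labels[rv] = LABEL_RV_BLOOD
    label_vol = LabelVolume(labels, spec.spacing, (0.0, 0.0, 0.0))

    infarct, mvo = _sector_masks(spec, wall, t)

    clean = _class_image(
        spec,
        labels,
        {
            LABEL_BACKGROUND: spec.mean_background,
            LABEL_LV_BLOOD: spec.mean_lv_blood,
            LABEL_LV_WALL: spec.mean_lv_wall,
            LABEL_RV_BLOOD: spec.mean_rv_blood,
        },
    )
    rng = np.random.default_rng([spec.seed, 0])
    values = clean + rng.normal(0.0, spec.noise_sigma, size=spec.shape) if spec.noise_sigma > 0 else clean.copy()
    vol = Volume3D(values, spec.spacing, (0.0, 0.0, 0.0))
    gt = GroundTruth(
        labels=label_vol,
        infarct_mask=infarct,
        mvo_mask=mvo,
        spec=spec,
        transmural_t=t,
        clean_values=clean,
    )
    return vol, gt


def _raised_cosine(x: np.ndarray, full: float, zero: float) -> np.ndarray:
    """1 for x <= full, 0 for x >= zero, raised-cosine ramp between."""
    if zero <= full:
        return (x <= full).astype(float)
    out = 0.5 * (1.0 + np.cos(np.pi * (x - full) / (zero - full)))
    return np.where(x <= full, 1.0, np.where(x >= zero, 0.0, out))


def displacement_at(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Ground-truth forward displacement (mm) baseline -> follow-up at world points.

    Radial expansion about the LV long axis with magnitude (s-1) * (in-plane
    distance from the axis) at the sector center, tapering as a raised cosine
    to zero at the angular and long-axis sector edges; identically zero outside
    the sector.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    c = spec.center_mm
    dx = pts[:, 0] - c[0]
    dy = pts[:, 1] - c[1]
    z = pts[:, 2] - c[2]
    d = np.hypot(dx, dy)
    theta = np.degrees(np.arctan2(dy, dx))
    dtheta = np.abs((theta - spec.sector_center_deg + 180.0) % 360.0 - 180.0)

    half = spec.sector_width_deg / 2.0
    ang = _raised_cosine(dtheta, half - spec.sector_taper_deg, half)

    zlo, zhi = spec.sector_z_mm
    mid = 0.5 * (zlo + zhi)
    halfz = 0.5 * (zhi - zlo)
    ztap = _raised_cosine(np.abs(z - mid), halfz - spec.sector_z_taper_mm, halfz)

    mag = (spec.expansion_factor - 1.0) * d * ang * ztap
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(d > 0, mag * dx / d, 0.0)
        uy = np.where(d > 0, mag * dy / d, 0.0)
    return np.stack([ux, uy, np.zeros_like(ux)], axis=1)


def make_followup(baseline: Volume3D, gt: GroundTruth, spec: PhantomSpec) -> tuple[Volume3D, np.ndarray]:
    """Warp the (noise-free) baseline through the sector-expansion field and re-add noise.

    The follow-up image is produced by inverse resampling — follow-up(y) =
    baseline(W^-1(y)) for W(x) = x + u(x) — so the *forward* field evaluated at
    baseline voxel centers is exactly the stored ground truth.  Noise is drawn
    independently of the baseline draw.

    Returns the follow-up volume and the forward displacement field
    (nx, ny, nz, 3) in mm, which is also stored on ``gt``.
    """
    if spec.expansion_factor < 0:
        raise ValidationError("expansion factor must be >= 0")
    if gt.clean_values is None:
        raise ValidationError("ground truth lacks the noise-free baseline; use make_lv_phantom")

    pts = baseline.grid_points()
    forward = displacement_at(pts, spec)

    if spec.expansion_factor == 1.0:
        warped = gt.clean_values.copy()
    else:
        # invert W(x) = x + u(x) by fixed-point iteration (u is smooth and small)
        x = pts.copy()
        for _ in range(25):
            x = pts - displacement_at(x, spec)
        clean_vol = Volume3D(gt.clean_values, spec.spacing, (0.0, 0.0, 0.0))
        vals, _ = sample_trilinear(clean_vol, x, background=spec.mean_background)
        warped = vals.reshape(spec.shape)

    rng = np.random.default_rng([spec.seed, 1])
    if spec.noise_sigma > 0:
        warped = warped + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    field = forward.reshape(spec.shape + (3,))
    gt.displacement_field = field
    return Volume3D(warped, spec.spacing, (0.0, 0.0, 0.0)), field


def make_lge(gt: GroundTruth, spec: PhantomSpec) -> Volume3D:
    """Late-gadolinium-enhancement-like volume: bimodal wall intensities (remote vs enhancing)."""
    labels = gt.labels.labels
    clean = _class_image(
        spec,
        labels,
        {
            LABEL_BACKGROUND: spec.mean_background,
            LABEL_LV_BLOOD: spec.lge_blood_mean,
            LABEL_LV_WALL: spec.lge_remote_mean,
            LABEL_RV_BLOOD: spec.lge_blood_mean,
        },
    )
    clean[gt.infarct_mask] = spec.lge_enhancing_mean
    rng = np.random.default_rng([spec.seed, 2])
    if spec.lge_sigma > 0:
        clean = clean + rng.normal(0.0, spec.lge_sigma, size=spec.shape)
    return Volume3D(clean, spec.spacing, (0.0, 0.0, 0.0))


def make_early_enhancement(gt: GroundTruth, spec: PhantomSpec) -> Volume3D:
    """Early post-contrast volume: enhancing infarct with an optional low-signal MVO core."""
    labels = gt.labels.labels
    clean = _class_image(
        spec,
        labels,
        {
            LABEL_BACKGROUND: spec.mean_background,
            LABEL_LV_BLOOD: spec.early_blood_mean,
            LABEL_LV_WALL: spec.early_remote_mean,
            LABEL_RV_BLOOD: spec.early_blood_mean,
        },
    )
    clean[gt.infarct_mask] = spec.early_enhancing_mean
    clean[gt.mvo_mask] = spec.early_mvo_mean
    rng = np.random.default_rng([spec.seed, 3])
    if spec.early_sigma > 0:
        clean = clean + rng.normal(0.0, spec.early_sigma, size=spec.shape)
    return Volume3D(clean, spec.spacing, (0.0, 0.0, 0.0))


def make_atlas(spec: PhantomSpec, blur_sigma_vox: float = 1.0) -> ProbabilisticAtlas:
    """Probabilistic atlas from a reference phantom: blurred class indicators, renormalized.

    The atlas carries the noise-free reference image as its intensity template
    for registration to a target.
    """
    ref_spec = dataclasses.replace(spec, noise_sigma=0.0)
    template, gt = make_lv_phantom(ref_spec)
    labels = gt.labels.labels
    probs = np.zeros((4,) + tuple(spec.shape), dtype=np.float64)
    for code in range(4):
        ind = (labels == code).astype(np.float64)
        probs[code] = gaussian_filter(ind, blur_sigma_vox) if blur_sigma_vox > 0 else ind
    total = probs.sum(axis=0)
    total[total == 0] = 1.0
    probs /= total
    return ProbabilisticAtlas(probs, np.asarray(spec.spacing, dtype=float), np.zeros(3), template)


# ---------------------------------------------------------------------------
# subjects and on-disk cohort layout
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    """All per-subject inputs plus ground truth (in memory)."""

    subject_id: str
    spec: PhantomSpec
    baseline: Volume3D
    followup: Volume3D
    lge: Volume3D
    early: Volume3D
    gt: GroundTruth


def make_subject(spec: PhantomSpec, subject_id: str = "subject") -> SubjectData:
    baseline, gt = make_lv_phantom(spec)
    lge = make_lge(gt, spec)
    early = make_early_enhancement(gt, spec)
    followup, _ = make_followup(baseline, gt, spec)
    return SubjectData(subject_id, spec, baseline, followup, lge, early, gt)


def write_subject(subject: SubjectData, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_volume(subject.baseline, d / "baseline.nii.gz")
    write_volume(subject.followup, d / "followup.nii.gz")
    write_volume(subject.lge, d / "lge.nii.gz")
    write_volume(subject.early, d / "early.nii.gz")
    write_labels(subject.gt.labels, d / "truth_labels.nii.gz")
    sp, orig = subject.gt.labels.spacing, subject.gt.labels.origin
    write_labels(LabelVolume(subject.gt.infarct_mask.astype(np.uint8), sp, orig), d / "truth_infarct.nii.gz")
    write_labels(LabelVolume(subject.gt.mvo_mask.astype(np.uint8), sp, orig), d / "truth_mvo.nii.gz")
    if subject.gt.displacement_field is not None:
        write_vector_field(subject.gt.displacement_field, sp, orig, d / "truth_field.nii.gz")
    (d / "manifest.json").write_text(subject.spec.to_json())


def read_subject(directory) -> SubjectData:
    d = Path(directory)
    spec = PhantomSpec.from_json((d / "manifest.json").read_text())
    labels = read_labels(d / "truth_labels.nii.gz")
    infarct = read_labels(d / "truth_infarct.nii.gz").labels.astype(bool)
    mvo = read_labels(d / "truth_mvo.nii.gz").labels.astype(bool)
    gt = GroundTruth(labels=labels, infarct_mask=infarct, mvo_mask=mvo, spec=spec)
    field_path = d / "truth_field.nii.gz"
    if field_path.exists():
        gt.displacement_field = read_vector_field(field_path)[0]
    return SubjectData(
        d.name,
        spec,
        read_volume(d / "baseline.nii.gz"),
        read_volume(d / "followup.nii.gz"),
        read_volume(d / "lge.nii.gz"),
        read_volume(d / "early.nii.gz"),
        gt,
    )
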