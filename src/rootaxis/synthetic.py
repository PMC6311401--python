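"""Synthetic tooth and cohort generation with known ground truth.

The study this package replicates compared software-predicted tooth root
axes against root axes measured on CBCT scans of 31 orthodontic patients.
That raw data (plaster-model scans and CBCT volumes) is not available, so
this module builds a stand-in with *known* truth:

* parametric anterior teeth (tapered, optionally apically curved roots
  with superellipse-like crowns) whose true root axis is known by
  construction;
* "predicted" roots whose axis deviates from the true axis by a
  controllable, recorded angle — emulating the proprietary virtual-root
  construction whose error the study measured;
* CBCT-style degradation: voxelisation at a configurable spacing
  (0.3 mm by default, the scanner's slice thickness) followed by
  isosurface extraction;
* whole cohorts (default 31 subjects x 12 anterior teeth) with per-arch
  rigid frame misalignment and subject metadata, all reproducible from a
  single seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import shapely
from scipy.spatial.transform import Rotation
from shapely.geometry import Polygon
from skimage.measure import marching_cubes

from .geometry import (
    DegeneracyWarning,
    GeometryError,
    Line3D,
    Plane,
    TriangleMesh,
    best_fit_line,
    plane_mesh_intersection,
)
from .register import RigidTransform
from .stl import read_stl, write_stl

__all__ = [
    "ANTERIOR_TEETH",
    "ToothShapeParams",
    "ToothModel",
    "VoxelVolume",
    "MetadataModel",
    "CohortSpec",
    "ToothPair",
    "SubjectRecord",
    "Cohort",
    "default_shape_params",
    "generate_tooth",
    "perturb_predicted_root",
    "voxelize",
    "extract_isosurface",
    "degrade_cbct_style",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
]

#: FDI codes of the permanent anterior teeth (quadrant digit 1-4,
#: position digit 1 central incisor, 2 lateral incisor, 3 canine).
ANTERIOR_TEETH = (11, 12, 13, 21, 22, 23, 31, 32, 33, 41, 42, 43)


def _fdi_position(label: int) -> int:
    q, p = divmod(int(label), 10)
    if q not in (1, 2, 3, 4) or p not in (1, 2, 3):
        raise GeometryError(f"{label} is not a permanent anterior FDI code")
    return p


def _is_upper(label: int) -> bool:
    return int(label) // 10 in (1, 2)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class ToothShapeParams:
    """Shape knobs for one parametric tooth (lengths in mm)."""

    root_length: float = 13.0
    cervical_radius_mesiodistal: float = 3.2
    cervical_radius_labiolingual: float = 3.6
    taper_exponent: float = 1.2
    apical_curve_deg: float = 0.0
    crown_height: float = 9.0
    mesh_resolution: int = 24  # segments per ring

    def validate(self) -> None:
        for name in ("root_length", "cervical_radius_mesiodistal",
                     "cervical_radius_labiolingual", "crown_height"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be > 0")
        if not (0.5 < self.taper_exponent <= 3.0):
            raise GeometryError("taper_exponent must be in (0.5, 3]")
        if not (0.0 <= self.apical_curve_deg <= 30.0):
            raise GeometryError("apical_curve_deg must be in [0, 30]")
        if self.mesh_resolution < 8:
            raise GeometryError("mesh_resolution must be >= 8")


@dataclass
class ToothModel:
    """One tooth: crown + root meshes, anatomical anchors, optional truth."""

    label: int
    crown: TriangleMesh
    root: TriangleMesh
    cervix_center: np.ndarray
    apex: np.ndarray
    true_axis: Optional[Line3D] = None

    def __post_init__(self) -> None:
        self.cervix_center = np.asarray(self.cervix_center, float).reshape(3)
        self.apex = np.asarray(self.apex, float).reshape(3)

    def root_length(self) -> float:
        return float(np.linalg.norm(self.apex - self.cervix_center))

    def transformed(self, t: RigidTransform) -> "ToothModel":
        return ToothModel(
            label=self.label,
            crown=self.crown.transformed(t.rotation, t.translation),
            root=self.root.transformed(t.rotation, t.translation),
            cervix_center=t.apply(self.cervix_center),
            apex=t.apply(self.apex),
            true_axis=self.true_axis.transformed(t.rotation, t.translation)
            if self.true_axis is not None
            else None,
        )


@dataclass
class VoxelVolume:
    """Scalar voxel grid emulating a (binarised) CBCT volume.

    ``values[i, j, k]`` is the sample at the voxel *centre*
    ``origin + (index + 0.5) * spacing``.
    """

    values: np.ndarray
    spacing: np.ndarray  # (3,) mm
    origin: np.ndarray  # (3,) mm, corner of voxel (0,0,0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing = np.broadcast_to(np.asarray(self.spacing, float).ravel(), (3,)).copy()
        self.origin = np.asarray(self.origin, float).reshape(3)
        if self.values.ndim != 3 or self.values.size == 0:
            raise GeometryError("voxel grid must be non-empty and 3D")
        if np.any(self.spacing <= 0):
            raise GeometryError("voxel spacing must be positive")


@dataclass
class MetadataModel:
    """Subject metadata distribution (defaults mirror the study cohort:
    10 of 31 male, ages 12-40 with mean 19.2 and SD 8.1 years)."""

    male_fraction: float = 10.0 / 31.0
    age_range: tuple[float, float] = (12.0, 40.0)
    age_mean: float = 19.2
    age_sd: float = 8.12
    angle_class_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``error_scale_deg`` maps FDI position digit (1 central incisor,
    2 lateral incisor, 3 canine) to the half-normal scale of the injected
    axis error for that tooth class; canines get the largest errors.
    """

    n_subjects: int = 31
    teeth: tuple[int, ...] = ANTERIOR_TEETH
    error_scale_deg: dict[int, float] = field(
        default_factory=lambda: {1: 12.0, 2: 15.0, 3: 20.0}
    )
    misalignment_rot_deg: float = 10.0
    misalignment_trans_mm: float = 5.0
    voxel_spacing: Optional[float] = 0.3  # None disables CBCT-style degradation
    jitter_sigma_mm: float = 0.05  # predicted-root vertex jitter; 0 disables
    seed: int = 0
    metadata_model: MetadataModel = field(default_factory=MetadataModel)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise GeometryError("n_subjects must be >= 1")
        if len(self.teeth) == 0:
            raise GeometryError("teeth list must not be empty")
        for t in self.teeth:
            _fdi_position(t)
        if any(v < 0 for v in self.error_scale_deg.values()):
            raise GeometryError("error_scale_deg must be >= 0")


@dataclass
class ToothPair:
    """One tooth in both frames, with the injected ground truth."""

    label: int
    predicted: ToothModel  # scanner (digital-model) frame
    cbct: ToothModel  # CBCT frame
    true_error_deg: float
    frame_transform: RigidTransform  # scanner frame -> CBCT frame


@dataclass
class SubjectRecord:
    subject_id: str
    sex: str
    age: float
    angle_class: str
    teeth: dict[int, ToothPair]


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[SubjectRecord]

    def n_tooth_pairs(self) -> int:
        return sum(len(s.teeth) for s in self.subjects)


# ---------------------------------------------------------------------------
# Single-tooth generation
# ---------------------------------------------------------------------------

_CLASS_DEFAULTS = {
    # position digit -> (root_length, r_md, r_ll, taper, apical_curve, crown_h)
    1: (13.0, 3.4, 3.6, 1.2, 3.0, 10.5),  # central incisor
    2: (13.5, 2.9, 3.2, 1.2, 5.0, 9.5),  # lateral incisor
    3: (16.5, 3.3, 4.0, 1.4, 8.0, 10.0),  # canine: longest, most curved
}


def default_shape_params(label: int) -> ToothShapeParams:
    """Typical shape parameters per anterior tooth class."""
    L, rmd, rll, taper, curve, ch = _CLASS_DEFAULTS[_fdi_position(label)]
    return ToothShapeParams(
        root_length=L,
        cervical_radius_mesiodistal=rmd,
        cervical_radius_labiolingual=rll,
        taper_exponent=taper,
        apical_curve_deg=curve,
        crown_height=ch,
    )


def _tube_mesh(rings: list[np.ndarray], top_center: np.ndarray, tip: np.ndarray) -> TriangleMesh:
    """Closed tube: fan cap at ``top_center``, ring strips, fan to ``tip``."""
    nc = len(rings[0])
    verts = [top_center[None, :]] + [np.asarray(r) for r in rings] + [tip[None, :]]
    vertices = np.vstack(verts)
    faces = []
    # top cap (center vertex 0, first ring 1..nc)
    base = 1
    for j in range(nc):
        faces.append([0, base + j, base + (j + 1) % nc])
    # side strips
    for i in range(len(rings) - 1):
        a, b = 1 + i * nc, 1 + (i + 1) * nc
        for j in range(nc):
            j2 = (j + 1) % nc
            faces.append([a + j, b + j, b + j2])
            faces.append([a + j, b + j2, a + j2])
    # tip fan
    last = 1 + (len(rings) - 1) * nc
    tip_idx = len(vertices) - 1
    for j in range(nc):
        faces.append([last + j, tip_idx, last + (j + 1) % nc])
    return TriangleMesh(vertices, np.array(faces))


def generate_tooth(label: int, params: ToothShapeParams | None = None, seed: int = 0) -> ToothModel:
    """Build one synthetic anterior tooth in its local frame.

    The cervix centre sits at the origin; the root extends toward -z as a
    tapered elliptical tube (radius scale ``(1-t)^taper``), optionally
    bent progressively over its apical third by ``apical_curve_deg``; the
    crown caps the cervix toward +z, sharing the cervical margin ring
    exactly.  The true root axis is the best-fit line through the ring
    centres of the cervical 80% of the root — the same anatomy the CBCT
    measurement targets.
    """
    params = params or default_shape_params(label)
    params.validate()
    rng = np.random.default_rng(seed)
    nc = params.mesh_resolution
    nr = max(16, nc)
    theta = 2 * np.pi * np.arange(nc) / nc

    # per-tooth morphological individuality (seeded, low frequency)
    lobe_phase = rng.uniform(0, 2 * np.pi, size=3)
    lobe_amp = rng.uniform(0.01, 0.04, size=3)

    def ring(center, e1, e2, a, b, u):
        bump = 1.0 + sum(
            lobe_amp[i] * np.sin((i + 2) * theta + lobe_phase[i]) for i in range(3)
        ) * np.clip(u, 0.0, 1.0)
        return (
            center
            + np.outer(np.cos(theta) * a * bump, e1)
            + np.outer(np.sin(theta) * b * bump, e2)
        )

    # --- root: integrate the (possibly curved) centre line ---------------
    L = params.root_length
    ts = np.arange(nr) / nr  # ring stations, t=1 is the apex tip
    centers = np.zeros((nr, 3))
    d = np.array([0.0, 0.0, -1.0])
    bend_axis = np.array([1.0, 0.0, 0.0])  # bend in the labiolingual plane
    pos = np.zeros(3)
    step = L / nr
    for i, t in enumerate(ts):
        centers[i] = pos
        if params.apical_curve_deg > 0 and t > 2.0 / 3.0:
            frac = (t - 2.0 / 3.0) / (1.0 / 3.0)
            ang = np.radians(params.apical_curve_deg) * frac
            d_i = Rotation.from_rotvec(bend_axis * ang).apply([0.0, 0.0, -1.0])
        else:
            d_i = d
        pos = pos + d_i * step
    apex = pos

    rings = []
    for i, t in enumerate(ts):
        scale = (1.0 - t) ** params.taper_exponent
        d_i = (centers[min(i + 1, nr - 1)] - centers[max(i - 1, 0)])
        d_i = d_i / np.linalg.norm(d_i)
        e1 = np.cross(d_i, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d_i, e1)
        rings.append(
            ring(
                centers[i],
                e1,
                e2,
                params.cervical_radius_mesiodistal * scale,
                params.cervical_radius_labiolingual * scale,
                u=t,
            )
        )
    root = _tube_mesh(rings, top_center=np.zeros(3), tip=apex)

    # truth over the cervical 80% — the region the measurements target
    true_axis = best_fit_line(centers[ts <= 0.8])

    # --- crown: blade-like tube sharing the cervical margin ring ----------
    # anterior crowns are strongly anisotropic: the labiolingual width
    # collapses toward an incisal edge while the mesiodistal width barely
    # tapers — this asymmetry is what makes rigid registration of crown
    # surfaces well-posed (a surface of revolution would leave rotation
    # about its own axis unobservable, as it would in a real scan of a
    # peg-shaped tooth)
    is_canine = _fdi_position(label) == 3
    ncr = max(8, nc // 2)
    us = np.arange(1, ncr + 1) / ncr  # u=0 is the shared cervical ring
    crown_rings = [rings[0]]  # exact shared margin
    h = params.crown_height
    e1, e2 = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
    for u in us[:-1]:
        bulge = 1.0 + 0.25 * np.sin(np.pi * u) ** 1.5
        # mesiodistal: widens then barely tapers; labiolingual: collapses
        a_scale = bulge * (1.0 - 0.25 * u**3)
        b_closure = np.sqrt(max(1.0 - u**1.8, 0.0))
        b_scale = bulge * (b_closure if not is_canine else 0.4 * b_closure + 0.6 * (1 - u) ** 1.2)
        # labial inclination of the crown face
        center = np.array(
            [0.0, 0.2 * params.cervical_radius_labiolingual * np.sin(np.pi * u), h * u]
        )
        crown_rings.append(
            ring(
                center,
                e1,
                e2,
                params.cervical_radius_mesiodistal * a_scale,
                params.cervical_radius_labiolingual * b_scale,
                u=1.0 - u,
            )
        )
    # incisal edge (canines keep a cusp tip offset mesially)
    tip_xy = np.array([0.4 * params.cervical_radius_mesiodistal, 0.0]) if is_canine else np.zeros(2)
    incisal_tip = np.array([tip_xy[0], tip_xy[1], h])
    crown = _tube_mesh(crown_rings, top_center=np.zeros(3), tip=incisal_tip)

    tooth = ToothModel(
        label=int(label),
        crown=crown,
        root=root,
        cervix_center=np.zeros(3),
        apex=apex,
        true_axis=true_axis,
    )
    tooth.crown.validate()
    tooth.root.validate()
    return tooth


# ---------------------------------------------------------------------------
# Predicted-root perturbation (the injected, known error)
# ---------------------------------------------------------------------------


def perturb_predicted_root(
    tooth: ToothModel,
    error_deg: float,
    azimuth_deg: float = 0.0,
    seed: int = 0,
    jitter_sigma_mm: float = 0.0,
) -> ToothModel:
    """Emulate a software-predicted root whose axis is off by ``error_deg``.

    The root mesh is rotated about an axis through the cervix centre,
    perpendicular to the true axis at the given azimuth, then optionally
    roughened with seeded Gaussian vertex jitter.  The crown is untouched.
    The returned model's ``true_axis`` is the rotated axis, so the angle
    between it and the source tooth's axis equals ``error_deg`` exactly
    (before jitter).
    """
    if not (0.0 <= error_deg <= 45.0):
        raise GeometryError("error_deg must be in [0, 45]")
    if tooth.true_axis is None:
        raise GeometryError("perturb_predicted_root needs a tooth with a known axis")
    u = tooth.true_axis.direction
    e1, e2 = Plane(tooth.cervix_center, u).basis()
    az = np.radians(azimuth_deg)
    w = np.cos(az) * e1 + np.sin(az) * e2
    R = Rotation.from_rotvec(w * np.radians(error_deg)).as_matrix()
    c = tooth.cervix_center

    def rot_pts(p):
        return (np.asarray(p, float) - c) @ R.T + c

    root_v = rot_pts(tooth.root.vertices)
    if jitter_sigma_mm > 0:
        rng = np.random.default_rng(seed)
        root_v = root_v + rng.normal(0.0, jitter_sigma_mm, size=root_v.shape)
    new_axis = Line3D(rot_pts(tooth.true_axis.anchor), R @ u)
    return ToothModel(
        label=tooth.label,
        crown=tooth.crown.copy(),
        root=TriangleMesh(root_v, tooth.root.faces.copy()),
        cervix_center=tooth.cervix_center.copy(),
        apex=rot_pts(tooth.apex),
        true_axis=new_axis,
    )


# ---------------------------------------------------------------------------
# CBCT-style degradation: voxelise -> threshold -> marching cubes
# ---------------------------------------------------------------------------


def voxelize(mesh: TriangleMesh, spacing: float) -> VoxelVolume:
    """Binary occupancy grid of a watertight mesh (1 = centre inside).

    Inside/outside is decided per axial slice: the mesh cross-section at
    each z-level of voxel centres is computed as closed outline loops and
    voxel centres take the even-odd parity of loop containment.  This is
    deterministic and exact up to the cross-section polygonisation.
    """
    if spacing <= 0:
        raise GeometryError("voxel spacing must be positive")
    open_edges = mesh.boundary_edge_count()
    if open_edges:
        raise GeometryError(
            f"voxelize requires a watertight mesh ({open_edges} open edges)"
        )
    lo, hi = mesh.bounds()
    origin = lo - 2.0 * spacing
    dims = np.ceil((hi - origin + 2.0 * spacing) / spacing).astype(int)
    values = np.zeros(dims, dtype=np.uint8)
    if (dims <= 4).any() or spacing > (hi - lo).max():
        if spacing > (hi - lo).max():
            warnings.warn(
                "voxel spacing exceeds the mesh extent; volume has no interior voxels",
                DegeneracyWarning,
                stacklevel=2,
            )
            return VoxelVolume(values, np.full(3, spacing), origin)

    xs = origin[0] + (np.arange(dims[0]) + 0.5) * spacing
    ys = origin[1] + (np.arange(dims[1]) + 0.5) * spacing
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    flat_x, flat_y = gx.ravel(), gy.ravel()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegeneracyWarning)
        for k in range(dims[2]):
            zc = origin[2] + (k + 0.5) * spacing
            if zc < lo[2] or zc > hi[2]:
                continue
            loops = plane_mesh_intersection(mesh, Plane([0, 0, zc], [0, 0, 1]))
            if not loops:
                continue
            parity = np.zeros(len(flat_x), dtype=bool)
            for loop in loops:
                poly = Polygon(loop.points[:, :2])
                if not poly.is_valid:
                    poly = poly.buffer(0)
                parity ^= shapely.contains_xy(poly, flat_x, flat_y)
            values[:, :, k] = parity.reshape(dims[0], dims[1])
    return VoxelVolume(values, np.full(3, spacing), origin)


def extract_isosurface(volume: VoxelVolume, threshold: float) -> TriangleMesh:
    """Marching-cubes surface of a voxel volume at the given iso-level,
    with vertices in mm (world coordinates)."""
    vals = volume.values.astype(np.float32)
    vmin, vmax = float(vals.min()), float(vals.max())
    if not (vmin < threshold < vmax):
        raise GeometryError(
            f"threshold {threshold} outside the volume's value range ({vmin}, {vmax})"
        )
    verts, faces, _, _ = marching_cubes(vals, level=threshold, spacing=tuple(volume.spacing))
    verts = verts + volume.origin + 0.5 * volume.spacing
    mesh = TriangleMesh(verts, faces)
    # marching cubes can emit the occasional degenerate sliver; drop it
    areas = mesh.face_areas()
    mesh = TriangleMesh(mesh.vertices, mesh.faces[areas > 1e-12])
    mesh.validate()
    return mesh


def degrade_cbct_style(
    mesh: TriangleMesh, spacing: float, psf_sigma_voxels: float = 0.7
) -> TriangleMesh:
    """Emulate a CBCT-derived surface: voxelise at ``spacing``, blur with
    a Gaussian point-spread function, and re-extract the 0.5 isosurface.

    The blur models the scanner's partial-volume graduation: a raw binary
    occupancy grid run through marching cubes carries a staircase bias
    (its area overestimates a smooth surface by ~8%), whereas real CBCT
    voxels take intermediate values at boundaries.  At the default sigma
    of 0.7 voxels the extracted sphere area is accurate to under 1%.
    """
    vol = voxelize(mesh, spacing)
    vals = vol.values.astype(np.float32)
    if psf_sigma_voxels > 0:
        from scipy.ndimage import gaussian_filter

        vals = gaussian_filter(vals, psf_sigma_voxels)
    return extract_isosurface(VoxelVolume(vals, vol.spacing, vol.origin), 0.5)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

_ARCH_RADIUS = 24.0  # mm, anterior arch curvature
_ARCH_ANGLES = {1: 8.0, 2: 24.0, 3: 40.0}  # degrees from midline per position


def _arch_pose(label: int, rng: np.random.Generator) -> RigidTransform:
    """Place a tooth (local frame: cervix at origin, crown +z) in the jaw."""
    pos = _fdi_position(label)
    q = label // 10
    sign = 1.0 if q in (1, 4) else -1.0  # patient's right vs left
    ang = np.radians(sign * _ARCH_ANGLES[pos])
    upper = _is_upper(label)
    # upper teeth: crowns point down (occlusal plane at z ~ 0)
    flip = Rotation.from_euler("x", 180, degrees=True) if upper else Rotation.identity()
    tip = Rotation.from_euler(
        "xy", rng.uniform(-5, 5, size=2), degrees=True
    )  # natural inclination scatter
    around = Rotation.from_euler("z", np.degrees(ang), degrees=True)
    R = (around * tip * flip).as_matrix()
    center = np.array(
        [_ARCH_RADIUS * np.sin(ang), _ARCH_RADIUS * np.cos(ang) - _ARCH_RADIUS, 0.0]
    )
    center[2] = 2.0 if upper else -2.0
    return RigidTransform(R, center)


def _random_rigid(rng: np.random.Generator, rot_deg: float, trans_mm: float) -> RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = rng.uniform(-rot_deg, rot_deg)
    R = Rotation.from_rotvec(axis * np.radians(ang)).as_matrix()
    t = rng.uniform(-trans_mm, trans_mm, size=3)
    return RigidTransform(R, t)


def _jittered_params(label: int, rng: np.random.Generator) -> ToothShapeParams:
    p = default_shape_params(label)
    return replace(
        p,
        root_length=p.root_length * rng.uniform(0.9, 1.1),
        cervical_radius_mesiodistal=p.cervical_radius_mesiodistal * rng.uniform(0.92, 1.08),
        cervical_radius_labiolingual=p.cervical_radius_labiolingual * rng.uniform(0.92, 1.08),
        apical_curve_deg=float(np.clip(p.apical_curve_deg * rng.uniform(0.5, 1.5), 0, 30)),
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full synthetic cohort with retained ground truth.

    Per subject: metadata drawn from the metadata model; per tooth a
    "predicted" model (scanner frame, root axis off by a half-normal
    injected error, optional vertex jitter) and a CBCT-style model
    (optionally voxelised and re-extracted at ``voxel_spacing``, then
    moved into the CBCT frame by a per-arch random rigid transform).
    """
    spec.validate()
    root_ss = np.random.SeedSequence(spec.seed)
    subject_seeds = root_ss.spawn(spec.n_subjects)
    subjects: list[SubjectRecord] = []
    md = spec.metadata_model
    for si, ss in enumerate(subject_seeds):
        rng = np.random.default_rng(ss)
        sex = "M" if rng.random() < md.male_fraction else "F"
        lo_a, hi_a = md.age_range
        age = float(np.clip(rng.normal(md.age_mean, md.age_sd), lo_a, hi_a))
        angle_class = ["I", "II", "III"][rng.choice(3, p=md.angle_class_probs)]
        arch_transforms = {
            "upper": _random_rigid(rng, spec.misalignment_rot_deg, spec.misalignment_trans_mm),
            "lower": _random_rigid(rng, spec.misalignment_rot_deg, spec.misalignment_trans_mm),
        }
        teeth: dict[int, ToothPair] = {}
        for label in spec.teeth:
            tooth_seed = int(rng.integers(0, 2**31 - 1))
            tooth = generate_tooth(label, _jittered_params(label, rng), seed=tooth_seed)
            pose = _arch_pose(label, rng)
            tooth = tooth.transformed(pose)

            scale = spec.error_scale_deg.get(_fdi_position(label), 0.0)
            err = float(min(abs(rng.normal(0.0, scale)) if scale > 0 else 0.0, 45.0))
            azimuth = float(rng.uniform(0.0, 360.0))
            predicted = perturb_predicted_root(
                tooth, err, azimuth, seed=tooth_seed + 1,
                jitter_sigma_mm=spec.jitter_sigma_mm,
            )

            if spec.voxel_spacing:
                cbct_local = ToothModel(
                    label=tooth.label,
                    crown=degrade_cbct_style(tooth.crown, spec.voxel_spacing),
                    root=degrade_cbct_style(tooth.root, spec.voxel_spacing),
                    cervix_center=tooth.cervix_center,
                    apex=tooth.apex,
                    true_axis=tooth.true_axis,
                )
            else:
                cbct_local = tooth
            arch = "upper" if _is_upper(label) else "lower"
            frame_t = arch_transforms[arch]
            teeth[label] = ToothPair(
                label=label,
                predicted=predicted,
                cbct=cbct_local.transformed(frame_t),
                true_error_deg=err,
                frame_transform=frame_t,
            )
        subjects.append(
            SubjectRecord(
                subject_id=f"S{si + 1:03d}",
                sex=sex,
                age=age,
                angle_class=angle_class,
                teeth=teeth,
            )
        )
    return Cohort(spec=spec, subjects=subjects)


# ---------------------------------------------------------------------------
# Cohort persistence (STL tree + manifest/metadata CSV)
# ---------------------------------------------------------------------------


def _model_row(model: ToothModel) -> dict:
    row = {
        "cervix_x": model.cervix_center[0],
        "cervix_y": model.cervix_center[1],
        "cervix_z": model.cervix_center[2],
        "apex_x": model.apex[0],
        "apex_y": model.apex[1],
        "apex_z": model.apex[2],
    }
    if model.true_axis is not None:
        a, d = model.true_axis.anchor, model.true_axis.direction
        row.update(
            axis_ax=a[0], axis_ay=a[1], axis_az=a[2],
            axis_dx=d[0], axis_dy=d[1], axis_dz=d[2],
        )
    return row


def save_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write a cohort as STL files + ``manifest.csv`` + ``metadata.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for subj in cohort.subjects:
        sdir = directory / subj.subject_id
        sdir.mkdir(exist_ok=True)
        for label, pair in subj.teeth.items():
            for frame, model in (("predicted", pair.predicted), ("cbct", pair.cbct)):
                crown_file = f"{subj.subject_id}/{frame}_{label}_crown.stl"
                root_file = f"{subj.subject_id}/{frame}_{label}_root.stl"
                write_stl(model.crown, directory / crown_file)
                write_stl(model.root, directory / root_file)
                row = {
                    "subject": subj.subject_id,
                    "tooth_fdi": label,
                    "frame": frame,
                    "crown_file": crown_file,
                    "root_file": root_file,
                    "true_error_deg": pair.true_error_deg,
                }
                row.update(_model_row(model))
                for i, v in enumerate(pair.frame_transform.to_params()):
                    row[f"t{i:02d}"] = v
                rows.append(row)
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False, float_format="%.9g")
    pd.DataFrame(
        [
            {"subject": s.subject_id, "sex": s.sex, "age": s.age, "angle_class": s.angle_class}
            for s in cohort.subjects
        ]
    ).to_csv(directory / "metadata.csv", index=False, float_format="%.9g")
    return directory


def _row_model(directory: Path, row: pd.Series) -> ToothModel:
    axis = None
    if "axis_dx" in row and pd.notna(row.get("axis_dx")):
        axis = Line3D(
            [row["axis_ax"], row["axis_ay"], row["axis_az"]],
            [row["axis_dx"], row["axis_dy"], row["axis_dz"]],
        )
    return ToothModel(
        label=int(row["tooth_fdi"]),
        crown=read_stl(directory / row["crown_file"]),
        root=read_stl(directory / row["root_file"]),
        cervix_center=[row["cervix_x"], row["cervix_y"], row["cervix_z"]],
        apex=[row["apex_x"], row["apex_y"], row["apex_z"]],
        true_axis=axis,
    )


def load_cohort(directory: str | Path, skip_missing: bool = True) -> Cohort:
    """Load a cohort previously written by :func:`save_cohort`.

    With ``skip_missing`` (the default), a subject whose mesh files are
    missing or unreadable is dropped with a warning and the rest of the
    cohort still loads; otherwise the error propagates.
    """
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv", comment="#")
    metadata = pd.read_csv(directory / "metadata.csv", comment="#").set_index("subject")
    subjects: list[SubjectRecord] = []
    for sid, sgroup in manifest.groupby("subject", sort=True):
        try:
            subjects.append(_load_subject(directory, str(sid), sgroup, metadata))
        except (OSError, GeometryError) as exc:
            if not skip_missing:
                raise
            warnings.warn(f"skipping subject {sid}: {exc}", UserWarning, stacklevel=2)
    return Cohort(spec=CohortSpec(n_subjects=max(len(subjects), 1)), subjects=subjects)


def _load_subject(
    directory: Path, sid: str, sgroup: pd.DataFrame, metadata: pd.DataFrame
) -> SubjectRecord:
    teeth: dict[int, ToothPair] = {}
    for label, tgroup in sgroup.groupby("tooth_fdi"):
        by_frame = {r["frame"]: r for _, r in tgroup.iterrows()}
        if set(by_frame) != {"predicted", "cbct"}:
            raise GeometryError(
                f"subject {sid} tooth {label}: need both frames, got {sorted(by_frame)}"
            )
        prow = by_frame["predicted"]
        teeth[int(label)] = ToothPair(
            label=int(label),
            predicted=_row_model(directory, prow),
            cbct=_row_model(directory, by_frame["cbct"]),
            true_error_deg=float(prow["true_error_deg"]),
            frame_transform=RigidTransform.from_params(
                [prow[f"t{i:02d}"] for i in range(12)]
            ),
        )
    meta = metadata.loc[sid]
    return SubjectRecord(
        subject_id=sid,
        sex=str(meta["sex"]),
        age=float(meta["age"]),
        angle_class=str(meta["angle_class"]),
        teeth=teeth,
    )
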