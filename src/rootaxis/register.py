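"""Rigid registration of the digital-model frame onto the CBCT frame.

The study's alignment is two-stage: a manual coarse alignment (emulated
here by corresponding landmarks solved in closed form with the Kabsch
algorithm) followed by automatic refinement with a trimmed, point-to-point
Iterative Closest Point (ICP) loop over crown surfaces.

Nearest correspondences are true closest points on the target surface
(vertex/edge/interior of the nearest triangle), found via a k-d tree over
triangle centroids with exact point-to-triangle projection on a candidate
set — required for sub-resolution accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import GeometryError, TriangleMesh, surface_sample_uniform

__all__ = [
    "RigidTransform",
    "ICPConfig",
    "RegistrationError",
    "landmark_align",
    "icp_refine",
    "closest_points_on_mesh",
]


class RegistrationError(GeometryError):
    """Raised when a registration problem is degenerate or diverges."""


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` (rotation + translation, mm)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)

    def validate(self, tol: float = 1e-9) -> None:
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=tol * 10):
            raise RegistrationError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=tol * 10):
            raise RegistrationError("rotation has determinant != +1 (reflection?)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Geodesic rotation angle of R, degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    # manifest serialisation: row-major 3x4
    def to_params(self) -> np.ndarray:
        return np.hstack([self.rotation, self.translation[:, None]]).ravel()

    @classmethod
    def from_params(cls, params: np.ndarray) -> "RigidTransform":
        m = np.asarray(params, dtype=np.float64).reshape(3, 4)
        return cls(m[:, :3], m[:, 3])


@dataclass
class ICPConfig:
    """Knobs for the trimmed ICP refinement.

    ``trim_fraction`` is the fraction of closest correspondences kept in
    each least-squares update; 1.0 recovers plain ICP.
    """

    max_iterations: int = 50
    rms_tolerance: float = 1e-6  # mm change in RMS that counts as converged
    trim_fraction: float = 0.9
    source_sample_count: int = 5000
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.trim_fraction <= 1.0):
            raise RegistrationError("trim_fraction must be in (0, 1]")
        if self.max_iterations < 1:
            raise RegistrationError("max_iterations must be >= 1")


# ---------------------------------------------------------------------------
# Kabsch landmark alignment
# ---------------------------------------------------------------------------


def landmark_align(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping source landmarks onto targets.

    Closed-form Kabsch solution: SVD of the cross-covariance of the centred
    point sets, with the reflection corrected so det(R) = +1.  Minimises
    ``sum ||R s_i + t - t_i||^2``.
    """
    s = np.asarray(source_points, dtype=np.float64).reshape(-1, 3)
    t = np.asarray(target_points, dtype=np.float64).reshape(-1, 3)
    if len(s) != len(t):
        raise RegistrationError(f"landmark count mismatch: {len(s)} vs {len(t)}")
    if len(s) < 3:
        raise RegistrationError("need at least 3 landmark pairs")
    sc, tc = s.mean(axis=0), t.mean(axis=0)
    s0, t0 = s - sc, t - tc
    # degenerate (collinear) sets give a rank-<2 cross-covariance
    if np.linalg.matrix_rank(s0, tol=1e-9) < 2:
        raise RegistrationError("landmarks are collinear or coincident")
    H = s0.T @ t0
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, tc - R @ sc)


# ---------------------------------------------------------------------------
# Closest point on a triangle mesh
# ---------------------------------------------------------------------------


class _SurfaceLocator:
    """k-d tree over triangle centroids + exact point-triangle projection."""

    def __init__(self, mesh: TriangleMesh, k_candidates: int = 12):
        mesh.validate()
        self.tri = mesh.triangles  # (m, 3, 3)
        self.k = min(k_candidates, len(self.tri))
        # guard radius: a true nearest triangle's centroid can be at most
        # (candidate centroid distance + max circumradius-ish extent) away;
        # with k candidates on dense meshes this is a safe approximation.
        self.tree = cKDTree(self.tri.mean(axis=1))

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        _, idx = self.tree.query(points, k=self.k)
        if self.k == 1:
            idx = idx[:, None]
        cand = self.tri[idx]  # (n, k, 3, 3)
        closest = _closest_point_on_triangles(points[:, None, :], cand)
        d2 = ((closest - points[:, None, :]) ** 2).sum(axis=2)
        best = np.argmin(d2, axis=1)
        rows = np.arange(len(points))
        return closest[rows, best], np.sqrt(d2[rows, best])


def _closest_point_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Vectorised closest point on triangles (Ericson's region method).

    ``p`` broadcasts against ``tri``'s leading axes; ``tri[..., 3, 3]``.
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    ab, ac, ap = b - a, c - a, p - a
    d1 = (ab * ap).sum(-1)
    d2 = (ac * ap).sum(-1)
    bp = p - b
    d3 = (ab * bp).sum(-1)
    d4 = (ac * bp).sum(-1)
    cp = p - c
    d5 = (ab * cp).sum(-1)
    d6 = (ac * cp).sum(-1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    denom_uv = d1 - d3
    v_ab = np.where(np.abs(denom_uv) > 0, d1 / np.where(denom_uv == 0, 1.0, denom_uv), 0.0)
    w_ac = np.where(np.abs(d2 - d6) > 0, d2 / np.where(d2 == d6, 1.0, d2 - d6), 0.0)
    den_bc = (d4 - d3) + (d5 - d6)
    w_bc = np.where(np.abs(den_bc) > 0, (d4 - d3) / np.where(den_bc == 0, 1.0, den_bc), 0.0)

    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v_in = vb / denom
    w_in = vc / denom

    out = a + v_in[..., None] * ab + w_in[..., None] * ac  # interior default

    # edge BC region
    w_bc_c = np.clip(w_bc, 0.0, 1.0)
    cond_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    out = np.where(cond_bc[..., None], b + w_bc_c[..., None] * (c - b), out)
    # edge AC region
    w_ac_c = np.clip(w_ac, 0.0, 1.0)
    cond_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(cond_ac[..., None], a + w_ac_c[..., None] * ac, out)
    # edge AB region
    v_ab_c = np.clip(v_ab, 0.0, 1.0)
    cond_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(cond_ab[..., None], a + v_ab_c[..., None] * ab, out)
    # vertex regions
    cond_c = (d6 >= 0) & (d5 <= d6)
    out = np.where(cond_c[..., None], c, out)
    cond_b = (d3 >= 0) & (d4 <= d3)
    out = np.where(cond_b[..., None], b, out)
    cond_a = (d1 <= 0) & (d2 <= 0)
    out = np.where(cond_a[..., None], a, out)
    return out


def closest_points_on_mesh(mesh: TriangleMesh, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest surface points and distances for a batch of query points."""
    return _SurfaceLocator(mesh).query(points)


# ---------------------------------------------------------------------------
# Trimmed ICP
# ---------------------------------------------------------------------------


def _transform_params(t: RigidTransform, align_to: np.ndarray | None = None) -> np.ndarray:
    """7-vector (unit quaternion + translation) for extrapolation in
    parameter space; the quaternion sign is aligned to a reference to keep
    successive deltas comparable."""
    from scipy.spatial.transform import Rotation

    q = Rotation.from_matrix(t.rotation).as_quat()
    if align_to is not None and float(q @ align_to[:4]) < 0:
        q = -q
    return np.concatenate([q, t.translation])


def _params_transform(p: np.ndarray) -> RigidTransform:
    from scipy.spatial.transform import Rotation

    q = p[:4] / np.linalg.norm(p[:4])
    return RigidTransform(Rotation.from_quat(q).as_matrix(), p[4:])


def icp_refine(
    source: TriangleMesh,
    target: TriangleMesh,
    init: RigidTransform,
    config: ICPConfig | None = None,
    rms_history: list | None = None,
) -> tuple[RigidTransform, float, int]:
    """Refine a rigid alignment of ``source`` onto ``target`` with trimmed ICP.

    Source points are area-uniform samples drawn once (seeded) and reused in
    every iteration; correspondences are exact closest points on the target
    surface; the closest ``trim_fraction`` of pairs feed a Kabsch update
    recomputed from the original samples (no incremental drift).

    Returns ``(transform, final_rms_mm, iterations)`` where the transform
    already composes ``init``.
    """
    config = config or ICPConfig()
    config.validate()
    init.validate()
    source.validate()
    target.validate()

    samples = surface_sample_uniform(source, config.source_sample_count, seed=config.seed)

    # sanity: initialisation must bring the bounding boxes into contact
    s_lo, s_hi = init.apply(source.vertices).min(0), init.apply(source.vertices).max(0)
    t_lo, t_hi = target.bounds()
    margin = 0.5 * max((t_hi - t_lo).max(), (s_hi - s_lo).max())
    if np.any(s_lo - margin > t_hi) or np.any(s_hi + margin < t_lo):
        raise RegistrationError(
            "source and target are disjoint after initialisation; "
            "provide a better initial transform (e.g. landmark_align)"
        )

    locator = _SurfaceLocator(target)
    current = init
    n_keep = max(3, int(round(config.trim_fraction * len(samples))))

    def correspond(t: RigidTransform):
        nearest, dist = locator.query(t.apply(samples))
        keep = np.argsort(dist)[:n_keep]
        return nearest, keep, float(np.sqrt(np.mean(dist[keep] ** 2)))

    prev_rms = np.inf
    prev_params = _transform_params(current)
    prev_delta: np.ndarray | None = None
    rms = np.inf
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        nearest, keep, rms = correspond(current)
        if rms_history is not None:
            rms_history.append(rms)
        if abs(prev_rms - rms) < config.rms_tolerance:
            break
        prev_rms = rms
        current = landmark_align(samples[keep], nearest[keep])

        # point-to-point ICP converges linearly under tangential sliding;
        # when successive parameter updates are nearly collinear with a
        # stable contraction ratio, jump to the geometric-series limit
        # (the acceleration step of the classical algorithm), keeping the
        # update only if it does not increase the RMS
        params = _transform_params(current, align_to=prev_params)
        delta = params - prev_params
        if prev_delta is not None:
            n_d, n_p = np.linalg.norm(delta), np.linalg.norm(prev_delta)
            if n_d > 0 and n_p > 0:
                cosang = float(delta @ prev_delta) / (n_d * n_p)
                ratio = n_d / n_p
                if cosang > 0.95 and 0.05 < ratio < 0.97:
                    factor = min(ratio / (1.0 - ratio), 25.0)
                    candidate = _params_transform(params + factor * delta)
                    _, _, rms_ext = correspond(candidate)
                    if rms_ext < rms:
                        current = candidate
                        delta = None  # restart the contraction estimate
        prev_delta = delta
        prev_params = _transform_params(current, align_to=prev_params)
    return current, rms, iterations
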