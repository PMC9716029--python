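"""Minimum liner-to-neck distance and the impingement predicate.

The liner rim is the circle of radius ``head_radius`` in the plane z = 0 of
the liner frame; the neck is a cylinder of radius ``neck_radius`` whose axis
passes through the origin (head center) along the unit direction ``d_l`` and
extends to ``neck_length``.  For a flat liner the minimum distance between
liner and neck is always attained at the rim, and by azimuthal symmetry it
depends on ``d_l`` only through its polar angle θ against the liner axis:

    min_distance = max(head_radius · cos θ − neck_radius, 0)

with contact (impingement) exactly when θ ≥ 90° − arcsin(neck_radius /
head_radius), i.e. half the oscillation angle.  A grid-sampling brute-force
distance is provided as the independent oracle for the closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .implant import ImplantSpec

__all__ = [
    "ClearanceResult",
    "neck_polar_angle_deg",
    "impingement_limit_angle",
    "liner_neck_distance",
    "impinges",
    "brute_force_distance",
]

_AZIMUTH_EPS = 1e-9


@dataclass(frozen=True)
class ClearanceResult:
    """Outcome of a single clearance evaluation.

    ``contact_side`` labels the rim sector nearest to the neck (anterior /
    posterior by the pelvis-frame anterior component of the nearest rim
    point) whether or not contact occurs; it is ``"none"`` only when the neck
    is coaxial with the liner and no sector is nearest.
    """

    min_distance: float
    impinged: bool
    contact_side: str
    neck_polar_angle: float


def neck_polar_angle_deg(d_l: np.ndarray) -> float:
    """Polar angle of the neck axis against the liner +z axis, degrees."""
    d_l = np.asarray(d_l, dtype=float)
    return math.degrees(math.acos(np.clip(d_l[2], -1.0, 1.0)))


def impingement_limit_angle(spec: ImplantSpec) -> float:
    """Polar angle at which the neck first contacts the rim (degrees).

    Equals half the oscillation angle: ``90° − arcsin(neck_radius/head_radius)``.
    """
    return 90.0 - math.degrees(math.asin(spec.neck_radius / spec.head_radius))


def _check_unit(d_l: np.ndarray) -> np.ndarray:
    d_l = np.asarray(d_l, dtype=float)
    if d_l.shape != (3,):
        raise ValueError(f"d_l must be a 3-vector, got shape {d_l.shape}")
    if abs(np.linalg.norm(d_l) - 1.0) > 1e-6:
        raise ValueError("d_l must be a unit vector")
    return d_l


def _contact_side(d_l: np.ndarray) -> str:
    # The liner-frame x-axis is the rim-plane projection of the pelvis
    # anterior axis, so the nearest rim point lies anterior iff d_l[0] > 0.
    if abs(d_l[0]) < _AZIMUTH_EPS and abs(d_l[1]) < _AZIMUTH_EPS:
        return "none"
    if d_l[0] > _AZIMUTH_EPS:
        return "anterior"
    if d_l[0] < -_AZIMUTH_EPS:
        return "posterior"
    return "none"


def liner_neck_distance(spec: ImplantSpec, d_l: np.ndarray) -> ClearanceResult:
    """Closed-form minimum distance between the liner rim and the neck surface.

    ``d_l`` is the head-to-shaft neck direction in the liner frame (unit
    vector, pointing out of the cup: polar angle below 180°).  The distance is
    clamped at 0 with ``impinged=True`` at or beyond rim contact.
    """
    d_l = _check_unit(d_l)
    theta = neck_polar_angle_deg(d_l)
    limit = impingement_limit_angle(spec)
    if theta >= limit - 1e-12:
        dist = 0.0
        imp = True
    else:
        dist = spec.head_radius * math.cos(math.radians(theta)) - spec.neck_radius
        imp = False
    return ClearanceResult(
        min_distance=dist,
        impinged=imp,
        contact_side=_contact_side(d_l),
        neck_polar_angle=theta,
    )


def impinges(spec: ImplantSpec, d_l: np.ndarray) -> bool:
    """True iff the neck axis polar angle is at or beyond the contact limit."""
    d_l = _check_unit(d_l)
    return neck_polar_angle_deg(d_l) >= impingement_limit_angle(spec) - 1e-12


def _min_pair_distance(p: np.ndarray, q: np.ndarray) -> tuple[float, int, int]:
    """Minimum pairwise Euclidean distance between point sets p (n,3), q (m,3)."""
    d2 = (
        np.sum(p**2, axis=1)[:, None]
        + np.sum(q**2, axis=1)[None, :]
        - 2.0 * (p @ q.T)
    )
    i, j = np.unravel_index(np.argmin(d2), d2.shape)
    return math.sqrt(max(d2[i, j], 0.0)), int(i), int(j)


def brute_force_distance(
    spec: ImplantSpec, d_l: np.ndarray, resolution: float = 0.05
) -> float:
    """Sampling oracle: min distance over rim-point × neck-surface-point grids.

    ``resolution`` sets the fine-stage step: degrees for the rim and cylinder
    azimuths, millimetres for the axial coordinate.  A coarse global pass
    locates the minimizing region; a fine local pass refines it, so the result
    converges to :func:`liner_neck_distance` as ``resolution → 0``.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    d_l = _check_unit(d_l)
    R = spec.head_radius
    r = spec.neck_radius
    L = spec.neck_length

    # Orthonormal basis (e1, e2) perpendicular to the neck axis.
    axis = d_l
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    def rim_points(phi: np.ndarray) -> np.ndarray:
        return R * np.column_stack([np.cos(phi), np.sin(phi), np.zeros_like(phi)])

    def neck_points(t: np.ndarray, psi: np.ndarray) -> np.ndarray:
        tt, pp = np.meshgrid(t, psi, indexing="ij")
        pts = (
            tt.ravel()[:, None] * axis[None, :]
            + r * np.cos(pp).ravel()[:, None] * e1[None, :]
            + r * np.sin(pp).ravel()[:, None] * e2[None, :]
        )
        return pts, tt.ravel(), pp.ravel()

    # Coarse pass.
    phi_step, t_step, psi_step = math.radians(2.0), 0.5, math.radians(4.0)
    phi = np.arange(0.0, 2 * math.pi, phi_step)
    t = np.arange(0.0, L + t_step / 2, t_step)
    psi = np.arange(0.0, 2 * math.pi, psi_step)
    q, tq, pq = neck_points(t, psi)
    _, i, j = _min_pair_distance(rim_points(phi), q)
    phi0, t0, psi0 = phi[i], tq[j], pq[j]

    # Fine pass around the coarse minimizer (window of ±2 coarse cells).
    fr = math.radians(resolution)
    phi_f = np.arange(phi0 - 2 * phi_step, phi0 + 2 * phi_step + fr / 2, fr)
    t_f = np.arange(
        max(t0 - 2 * t_step, 0.0), min(t0 + 2 * t_step, L) + resolution / 2, resolution
    )
    psi_f = np.arange(psi0 - 2 * psi_step, psi0 + 2 * psi_step + fr / 2, fr)
    qf, _, _ = neck_points(t_f, psi_f)
    dist, _, _ = _min_pair_distance(rim_points(phi_f), qf)
    return dist
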