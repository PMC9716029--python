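"""Coordinate conventions and rotation composition.

All frames are right-handed.  The pelvis frame is aligned with the anterior
pelvic plane (APP): +x toward the patient's right, +y anterior, +z superior;
the APP is the x-z plane.  The femur frame coincides with the pelvis frame in
the neutral pose, with the shaft axis along +z and the posterior condylar
line parallel to x.

Sign conventions are side-neutral: flexion +, extension −; adduction +,
abduction −; internal rotation +, external −.  For left hips the lateral
direction is −x, handled by mirroring the cup and neck axes and by the ±1
factor inside :func:`hip_rotation`; the same pose angles describe the same
physical motion on either side.

Cup orientation uses the radiographic (Murray) definitions: anteversion is
the angle between the cup-opening axis and the coronal plane, inclination the
angle of the coronal-plane projection of that axis with the longitudinal
axis.

Hip poses compose as intrinsic Cardan rotations in the x-y-z order
(flexion/extension, then adduction/abduction, then internal/external
rotation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial.transform import Rotation

from .implant import ImplantSpec

__all__ = [
    "Side",
    "ComponentOrientation",
    "HipPose",
    "cup_axis",
    "cup_angles_from_axis",
    "liner_frame",
    "neck_axis_in_femur",
    "hip_rotation",
    "neck_axis_in_liner",
]

Side = Literal["right", "left"]

_ORTHO_TOL = 1e-9


def _side_sign(side: str) -> float:
    if side == "right":
        return 1.0
    if side == "left":
        return -1.0
    raise ValueError(f"side must be 'right' or 'left', got {side!r}")


@dataclass(frozen=True)
class ComponentOrientation:
    """Per-hip cup and stem orientation (degrees, radiographic definitions)."""

    cup_inclination: float
    cup_anteversion: float
    stem_anteversion: float
    side: str = "right"

    def __post_init__(self) -> None:
        _side_sign(self.side)
        if not 0 <= self.cup_inclination < 90:
            raise ValueError(
                f"cup_inclination must lie in [0, 90), got {self.cup_inclination}"
            )
        if not -90 < self.cup_anteversion < 90:
            raise ValueError(
                f"cup_anteversion must lie in (-90, 90), got {self.cup_anteversion}"
            )
        if not -90 < self.stem_anteversion < 90:
            raise ValueError(
                f"stem_anteversion must lie in (-90, 90), got {self.stem_anteversion}"
            )

    @property
    def combined_anteversion(self) -> float:
        """Sum of cup and stem anteversion (the CA of the combined-anteversion technique)."""
        return self.cup_anteversion + self.stem_anteversion


@dataclass(frozen=True)
class HipPose:
    """Hip joint angles in degrees, side-neutral signs.

    flexion + / extension −;  adduction + / abduction −;
    internal rotation + / external rotation −.
    """

    flexion: float
    adduction: float
    internal_rotation: float

    def __post_init__(self) -> None:
        for name in ("flexion", "adduction", "internal_rotation"):
            v = getattr(self, name)
            if not -180 < v <= 180:
                raise ValueError(f"{name} must lie in (-180, 180], got {v}")


def cup_axis(orientation: ComponentOrientation) -> np.ndarray:
    """Outward unit vector along the cup-opening axis, pelvis frame.

    For a right hip with radiographic inclination RI and anteversion RA the
    axis is ``(sin RI · cos RA, sin RA, −cos RI · cos RA)``; left hips mirror
    the lateral (x) component.  RA is recovered as ``arcsin(n_y)`` and RI as
    the angle of the coronal projection with the longitudinal axis.
    """
    ri = math.radians(orientation.cup_inclination)
    ra = math.radians(orientation.cup_anteversion)
    m = _side_sign(orientation.side)
    return np.array(
        [
            m * math.sin(ri) * math.cos(ra),
            math.sin(ra),
            -math.cos(ri) * math.cos(ra),
        ]
    )


def cup_angles_from_axis(n: np.ndarray, side: str = "right") -> tuple[float, float]:
    """Inverse of :func:`cup_axis`: radiographic (inclination, anteversion) in degrees."""
    n = np.asarray(n, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-6:
        raise ValueError("cup axis must be a unit vector")
    m = _side_sign(side)
    ra = math.degrees(math.asin(np.clip(n[1], -1.0, 1.0)))
    ri = math.degrees(math.atan2(m * n[0], -n[2]))
    return ri, ra


def liner_frame(orientation: ComponentOrientation) -> np.ndarray:
    """Rotation matrix (liner → pelvis): columns are the liner basis vectors.

    Column 3 is the cup-opening axis; column 1 is the normalized projection of
    the pelvis anterior axis (+y) onto the rim plane, fixing the azimuth
    origin used for anterior/posterior contact labeling; column 2 completes
    the right-handed basis.
    """
    n = cup_axis(orientation)
    y = np.array([0.0, 1.0, 0.0])
    proj = y - (y @ n) * n
    norm = np.linalg.norm(proj)
    if norm < 1e-9:
        raise ValueError(
            "liner frame is degenerate: cup axis parallel to the anterior axis"
        )
    c1 = proj / norm
    c2 = np.cross(n, c1)
    return np.column_stack([c1, c2, n])


def neck_axis_in_femur(
    spec: ImplantSpec, stem_anteversion: float, side: str = "right"
) -> np.ndarray:
    """Head-to-shaft unit direction of the prosthetic neck axis, femur frame.

    With neck-shaft angle γ and stem anteversion α the shaft-to-head
    direction for a right hip is
    ``v = (−sin(180°−γ)·cos α, sin(180°−γ)·sin α, cos(180°−γ))`` — the neck
    points medial/anterior/superior toward the head; left hips mirror x.
    The returned head-to-shaft direction is ``−v``.
    """
    g = math.radians(180.0 - spec.neck_shaft_angle)
    a = math.radians(stem_anteversion)
    m = _side_sign(side)
    v = np.array([-m * math.sin(g) * math.cos(a), math.sin(g) * math.sin(a), math.cos(g)])
    return -v / np.linalg.norm(v)


def hip_rotation(pose: HipPose, side: str = "right") -> np.ndarray:
    """Femur → pelvis rotation for a pose, intrinsic Cardan x-y-z order.

    ``R = Rx(flexion) · Ry(s·adduction) · Rz(s·internal_rotation)`` with
    s = +1 (right) or −1 (left), so positive adduction moves the distal femur
    medially and positive internal rotation turns the anterior femur medially
    on either side.  At 90° flexion the distal femur (−z) maps to the pelvis
    anterior axis (+y).
    """
    s = _side_sign(side)
    if abs(abs(pose.adduction) - 90.0) < 1e-9:
        raise ValueError(
            "gimbal degeneracy: |adduction| = 90 degrees is outside the supported range"
        )
    return Rotation.from_euler(
        "XYZ",
        [pose.flexion, s * pose.adduction, s * pose.internal_rotation],
        degrees=True,
    ).as_matrix()


def neck_axis_in_liner(
    spec: ImplantSpec, orientation: ComponentOrientation, pose: HipPose
) -> np.ndarray:
    """Neck-axis (head-to-shaft) unit direction expressed in the liner frame."""
    d_f = neck_axis_in_femur(spec, orientation.stem_anteversion, orientation.side)
    d_p = hip_rotation(pose, orientation.side) @ d_f
    d_l = liner_frame(orientation).T @ d_p
    return d_l / np.linalg.norm(d_l)
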