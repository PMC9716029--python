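"""Parametric prosthesis geometry and closed-form range-of-motion limits.

The prosthesis is modeled as a ball-and-socket articulation:

* a spherical femoral head of diameter ``head_diameter`` seated concentrically
  in a *flat* hemispherical polyethylene liner of the same inner radius, whose
  rim circle lies in the equatorial plane through the head center;
* a cylindrical stem neck of diameter ``neck_diameter`` emanating from the
  head center along the neck axis and truncated at ``neck_length``.

For this geometry the impingement-free travel of the neck axis between
opposite-side rim contacts — the *oscillation angle* — has the closed form
``180° − 2·arcsin(neck_radius / head_radius)``, so it grows with the
head-neck ratio.  A sampling-based contact sweep is provided as an
independent check of that formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ImplantSpec",
    "make_implant_spec",
    "DEFAULT_IMPLANT",
    "oscillation_angle",
    "oscillation_angle_by_sweep",
]


@dataclass(frozen=True)
class ImplantSpec:
    """Fixed prosthesis geometry (lengths in mm, angles in degrees)."""

    head_diameter: float
    neck_diameter: float
    neck_shaft_angle: float
    neck_length: float = 40.0
    liner_type: str = "flat"

    def __post_init__(self) -> None:
        if self.liner_type != "flat":
            raise ValueError(
                f"liner_type: only 'flat' liners are supported, got {self.liner_type!r}"
            )
        if not self.head_diameter > 0:
            raise ValueError(f"head_diameter must be positive, got {self.head_diameter}")
        if not 0 < self.neck_diameter < self.head_diameter:
            raise ValueError(
                "neck_diameter must satisfy 0 < neck_diameter < head_diameter, "
                f"got neck_diameter={self.neck_diameter}, head_diameter={self.head_diameter}"
            )
        if not 90 < self.neck_shaft_angle < 180:
            raise ValueError(
                f"neck_shaft_angle must lie in (90, 180) degrees, got {self.neck_shaft_angle}"
            )
        if not self.neck_length > self.head_diameter / 2:
            raise ValueError(
                "neck_length must exceed the head radius, "
                f"got neck_length={self.neck_length}, head radius={self.head_diameter / 2}"
            )

    @property
    def head_radius(self) -> float:
        return self.head_diameter / 2.0

    @property
    def neck_radius(self) -> float:
        return self.neck_diameter / 2.0

    @property
    def head_neck_ratio(self) -> float:
        return self.head_diameter / self.neck_diameter


def make_implant_spec(
    head_diameter: float,
    neck_diameter: float,
    neck_shaft_angle: float,
    neck_length: float = 40.0,
) -> ImplantSpec:
    """Validate and build an :class:`ImplantSpec`."""
    return ImplantSpec(
        head_diameter=float(head_diameter),
        neck_diameter=float(neck_diameter),
        neck_shaft_angle=float(neck_shaft_angle),
        neck_length=float(neck_length),
    )


#: The study implant: 32 mm alumina head on a 9 mm neck, 130 degree neck-shaft
#: angle (head-neck ratio 3.56), flat liner.
DEFAULT_IMPLANT = make_implant_spec(32.0, 9.0, 130.0, 40.0)


def oscillation_angle(spec: ImplantSpec) -> float:
    """Closed-form oscillation angle of the neck inside a flat liner, degrees.

    Total angular travel of the neck axis between opposite-side rim contacts:
    ``180 − 2·arcsin(neck_radius / head_radius)``.
    """
    ratio = spec.neck_radius / spec.head_radius
    return 180.0 - 2.0 * math.degrees(math.asin(ratio))


def oscillation_angle_by_sweep(
    spec: ImplantSpec,
    step_deg: float = 0.01,
    axial_step: float = 0.02,
    azimuth_step_deg: float = 0.5,
) -> float:
    """Sampling oracle for :func:`oscillation_angle`.

    Tilts the neck axis away from the liner axis in increments of
    ``step_deg`` and reports twice the first tilt at which any sampled
    neck-surface point penetrates the liner material (below the rim plane and
    radially outside the liner sphere).  Runs a coarse 1-degree pass first and
    refines only the bracketing degree, which leaves the detection identical
    to a full fine sweep.
    """
    R = spec.head_radius
    r = spec.neck_radius
    # Neck surface sample points for axis along +z: (c, r*sin(psi), t) with
    # c = r*cos(psi); under a tilt by theta in the x-z plane the point moves to
    # z = t*cos(theta) - c*sin(theta) while |q|^2 = t^2 + r^2 stays fixed.
    t = np.arange(0.0, spec.neck_length + axial_step / 2, axial_step)
    psi = np.deg2rad(np.arange(0.0, 360.0, azimuth_step_deg))
    tt, cc = np.meshgrid(t, r * np.cos(psi), indexing="ij")
    outside = tt**2 + r**2 > R**2  # only points outside the head sphere can contact
    tt = tt[outside]
    cc = cc[outside]

    def penetrates(theta_deg: float) -> bool:
        th = math.radians(theta_deg)
        return bool(np.any(tt * math.cos(th) - cc * math.sin(th) < 0.0))

    coarse = 1.0
    theta = 0.0
    while theta <= 90.0 and not penetrates(theta):
        theta += coarse
    lo = max(theta - coarse, 0.0)
    theta = lo
    while theta <= 90.0 and not penetrates(theta):
        theta += step_deg
    return 2.0 * theta
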