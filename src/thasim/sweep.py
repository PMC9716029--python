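"""Virtual rotation × adduction sweeps at actual maximum flexion/extension.

The study's virtual experiment: for each hip, keep the measured flexion at
the posture (maximum flexion or maximum extension of the squat), *replace*
the measured adduction and rotation with grid values — internal rotation
0–60° in 15° steps at maximum flexion, external rotation 0–60° at maximum
extension, adduction −20–20° in 10° steps at both — and evaluate the
liner-to-neck clearance at every grid cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clearance import impinges, liner_neck_distance
from .cohort import Cohort
from .frames import ComponentOrientation, HipPose, neck_axis_in_liner
from .implant import ImplantSpec

__all__ = [
    "SweepGrid",
    "DEFAULT_ROTATIONS",
    "DEFAULT_ADDABD",
    "DistanceSurface",
    "CohortSweepResult",
    "sweep_hip",
    "cohort_sweep",
    "rotation_to_impingement",
]

DEFAULT_ROTATIONS: tuple[float, ...] = (0.0, 15.0, 30.0, 45.0, 60.0)
DEFAULT_ADDABD: tuple[float, ...] = (-20.0, -10.0, 0.0, 10.0, 20.0)

POSTURES = ("max_flexion", "max_extension")


@dataclass(frozen=True)
class SweepGrid:
    """Rotation magnitudes and adduction values (degrees, adduction +).

    Rotation magnitudes are applied as internal rotation at maximum flexion
    and as external rotation at maximum extension.
    """

    rotation_values: tuple[float, ...] = DEFAULT_ROTATIONS
    addabd_values: tuple[float, ...] = DEFAULT_ADDABD
    posture: str = "max_flexion"

    def __post_init__(self) -> None:
        if self.posture not in POSTURES:
            raise ValueError(f"posture must be one of {POSTURES}, got {self.posture!r}")
        for name, vals in (
            ("rotation_values", self.rotation_values),
            ("addabd_values", self.addabd_values),
        ):
            if len(vals) == 0:
                raise ValueError(f"{name} must be nonempty")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be strictly increasing, got {vals}")


@dataclass(frozen=True)
class DistanceSurface:
    """Clearance over a sweep grid for one hip.

    ``distances[i, j]`` is the minimum liner-to-neck distance (mm) at
    ``rotation_values[i]`` × ``addabd_values[j]``; ``impinged`` flags cells at
    zero distance.
    """

    grid: SweepGrid
    distances: np.ndarray
    impinged: np.ndarray
    hip_id: str

    def __post_init__(self) -> None:
        shape = (len(self.grid.rotation_values), len(self.grid.addabd_values))
        if self.distances.shape != shape or self.impinged.shape != shape:
            raise ValueError("surface shapes must match the grid dimensions")
        if not np.array_equal(self.impinged, self.distances == 0.0):
            raise ValueError("impinged must flag exactly the zero-distance cells")


def _rotation_sign(posture: str) -> float:
    # Internal rotation (+) is swept at maximum flexion, external (−) at
    # maximum extension.
    return 1.0 if posture == "max_flexion" else -1.0


def sweep_hip(
    spec: ImplantSpec,
    orientation: ComponentOrientation,
    pose_at_posture: HipPose,
    grid: SweepGrid,
) -> DistanceSurface:
    """Evaluate the clearance surface for one hip.

    The measured flexion at the posture is retained; measured adduction and
    rotation are replaced by the grid values (replacement, not offset).
    """
    if pose_at_posture is None:
        raise ValueError("pose_at_posture is required")
    sgn = _rotation_sign(grid.posture)
    nr, na = len(grid.rotation_values), len(grid.addabd_values)
    dist = np.empty((nr, na))
    for i, rot in enumerate(grid.rotation_values):
        for j, add in enumerate(grid.addabd_values):
            pose = HipPose(
                flexion=pose_at_posture.flexion,
                adduction=add,
                internal_rotation=sgn * rot,
            )
            d_l = neck_axis_in_liner(spec, orientation, pose)
            dist[i, j] = liner_neck_distance(spec, d_l).min_distance
    return DistanceSurface(
        grid=grid, distances=dist, impinged=dist == 0.0, hip_id="unnamed"
    )


@dataclass(frozen=True)
class CohortSweepResult:
    """Per-hip surfaces plus per-cell impingement rates for both postures."""

    surfaces: dict[str, tuple[DistanceSurface, ...]]
    hip_ids: tuple[str, ...] = field(default_factory=tuple)

    def grid(self, posture: str) -> SweepGrid:
        return self.surfaces[posture][0].grid

    def distances(self, posture: str) -> np.ndarray:
        """Stacked distances, shape (n_hips, n_rotations, n_addabd)."""
        return np.stack([s.distances for s in self.surfaces[posture]])

    def impinged_at(self, posture: str, rotation: float, addabd: float) -> np.ndarray:
        """Boolean per-hip impingement flags at one grid cell."""
        g = self.grid(posture)
        i = g.rotation_values.index(rotation)
        j = g.addabd_values.index(addabd)
        return np.array([s.impinged[i, j] for s in self.surfaces[posture]])

    def rates(self, posture: str) -> pd.DataFrame:
        """Fraction of hips impinged per grid cell (long format)."""
        g = self.grid(posture)
        imp = np.stack([s.impinged for s in self.surfaces[posture]])
        rows = []
        for i, rot in enumerate(g.rotation_values):
            for j, add in enumerate(g.addabd_values):
                rows.append(
                    {
                        "posture": posture,
                        "rotation_deg": rot,
                        "addabd_deg": add,
                        "impingement_rate": float(imp[:, i, j].mean()),
                        "n_impinged": int(imp[:, i, j].sum()),
                        "n_hips": imp.shape[0],
                    }
                )
        return pd.DataFrame(rows)

    def long_table(self) -> pd.DataFrame:
        """All cells of all hips: hip_id, posture, rotation, addabd, distance, impinged."""
        rows = []
        for posture, surfaces in self.surfaces.items():
            for s in surfaces:
                g = s.grid
                for i, rot in enumerate(g.rotation_values):
                    for j, add in enumerate(g.addabd_values):
                        rows.append(
                            {
                                "hip_id": s.hip_id,
                                "posture": posture,
                                "rotation_deg": rot,
                                "addabd_deg": add,
                                "distance_mm": s.distances[i, j],
                                "impinged": bool(s.impinged[i, j]),
                            }
                        )
        return pd.DataFrame(rows)


def cohort_sweep(
    spec: ImplantSpec,
    cohort: Cohort,
    grids: dict[str, SweepGrid] | None = None,
) -> CohortSweepResult:
    """Sweep every hip of a cohort at both postures."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if grids is None:
        grids = {p: SweepGrid(posture=p) for p in POSTURES}
    surfaces: dict[str, tuple[DistanceSurface, ...]] = {}
    for posture, grid in grids.items():
        per_hip = []
        for hip in cohort:
            pose = (
                hip.pose_max_flexion if posture == "max_flexion" else hip.pose_max_extension
            )
            s = sweep_hip(spec, hip.orientation, pose, grid)
            per_hip.append(
                DistanceSurface(
                    grid=s.grid,
                    distances=s.distances,
                    impinged=s.impinged,
                    hip_id=hip.hip_id,
                )
            )
        surfaces[posture] = tuple(per_hip)
    return CohortSweepResult(
        surfaces=surfaces, hip_ids=tuple(h.hip_id for h in cohort)
    )


def rotation_to_impingement(
    spec: ImplantSpec,
    orientation: ComponentOrientation,
    pose_at_posture: HipPose,
    addabd: float,
    posture: str,
    max_rotation: float = 120.0,
    tol: float = 0.01,
) -> float:
    """Smallest rotation magnitude producing impingement at a given adduction.

    Bisects on the rotation magnitude (internal at maximum flexion, external
    at maximum extension) to ``tol`` degrees; returns 0 when the hip is
    already impinged at zero rotation and ``inf`` when no rotation up to
    ``max_rotation`` impinges.
    """
    sgn = _rotation_sign(posture)

    def impinged_at(mag: float) -> bool:
        pose = HipPose(
            flexion=pose_at_posture.flexion,
            adduction=addabd,
            internal_rotation=sgn * mag,
        )
        return impinges(spec, neck_axis_in_liner(spec, orientation, pose))

    if impinged_at(0.0):
        return 0.0
    if not impinged_at(max_rotation):
        return math.inf
    lo, hi = 0.0, max_rotation
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if impinged_at(mid):
            hi = mid
        else:
            lo = mid
    return hi
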