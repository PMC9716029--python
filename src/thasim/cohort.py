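"""Seeded synthetic cohort emulating the study population.

The raw per-hip records of the squatting study are not public; this module
generates a stand-in cohort with the published statistical structure: each
variable is drawn from a truncated normal matching the printed
mean ± SD (range), and cup and stem anteversion are drawn jointly through a
Gaussian copula with a negative correlation so that combined anteversion
concentrates near the 40–60° surgical target without hard clipping.

Component-orientation targets (degrees):

* cup inclination 38.1 ± 5.8 (27–48)
* cup anteversion 16.4 ± 6.0 (4–32)
* stem anteversion 33.6 ± 11.4 (7–60)

Pose targets at maximum flexion / maximum extension during squatting, stored
here in the side-neutral sign convention (adduction +, internal rotation +);
the published table uses abduction + and is negated on import/export via the
``table2`` CSV dialect:

* flexion 80.7 ± 12.3 (60.6–114.2) / 1.6 ± 8.4 (−13.0–20.7)
* adduction −7.3 ± 5.4 (−17.7–−1.1) / −3.6 ± 3.1 (−10.7–4.5)
* rotation −22.7 ± 11.4 (−40.6–2.2) / −10.0 ± 6.5 (−28.7–1.2)

The published max-extension adduction/abduction row prints a mean outside its
own range (3.6 ± 3.1 with range −4.5–1.4, abduction-positive), presumably a
typographical slip; the default here widens the range just enough to cover
the mean and warns when used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .frames import ComponentOrientation, HipPose

__all__ = [
    "TruncatedNormal",
    "CohortConfig",
    "HipRecord",
    "Cohort",
    "generate_cohort",
    "cohort_summary",
    "write_cohort_csv",
    "read_cohort_csv",
    "COHORT_COLUMNS",
    "DEFAULT_VARIABLES",
]


@dataclass(frozen=True)
class TruncatedNormal:
    """Truncated-normal marginal: mean/sd of the parent normal, hard range."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if not self.lower < self.upper:
            raise ValueError(
                f"infeasible truncation: lower={self.lower} must be < upper={self.upper}"
            )

    @property
    def _ab(self) -> tuple[float, float]:
        return (self.lower - self.mean) / self.sd, (self.upper - self.mean) / self.sd

    def ppf(self, u: np.ndarray) -> np.ndarray:
        a, b = self._ab
        return truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)

    def cdf(self, x: np.ndarray) -> np.ndarray:
        a, b = self._ab
        return truncnorm.cdf(x, a, b, loc=self.mean, scale=self.sd)


#: Printed table values, side-neutral sign convention (see module docstring).
DEFAULT_VARIABLES: dict[str, TruncatedNormal] = {
    "cup_inclination": TruncatedNormal(38.1, 5.8, 27.0, 48.0),
    "cup_anteversion": TruncatedNormal(16.4, 6.0, 4.0, 32.0),
    "stem_anteversion": TruncatedNormal(33.6, 11.4, 7.0, 60.0),
    "flex_maxflex": TruncatedNormal(80.7, 12.3, 60.6, 114.2),
    "add_maxflex": TruncatedNormal(-7.3, 5.4, -17.7, -1.1),
    "rot_maxflex": TruncatedNormal(-22.7, 11.4, -40.6, 2.2),
    "flex_maxext": TruncatedNormal(1.6, 8.4, -13.0, 20.7),
    # Published row is internally inconsistent (mean outside range); range
    # widened to cover the mean. generate_cohort warns when this default is used.
    "add_maxext": TruncatedNormal(-3.6, 3.1, -10.7, 4.5),
    "rot_maxext": TruncatedNormal(-10.0, 6.5, -28.7, 1.2),
}

_INCONSISTENT_DEFAULT = "add_maxext"

_VARIABLE_ORDER = list(DEFAULT_VARIABLES)


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults reproduce the published cohort."""

    n: int = 32
    seed: int = 0
    variables: dict[str, TruncatedNormal] = field(
        default_factory=lambda: dict(DEFAULT_VARIABLES)
    )
    ca_correlation: float = -0.3

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"cohort size n must be positive, got {self.n}")
        if not -1.0 < self.ca_correlation <= 0.0:
            raise ValueError(
                f"ca_correlation must lie in (-1, 0], got {self.ca_correlation}"
            )
        missing = set(_VARIABLE_ORDER) - set(self.variables)
        if missing:
            raise ValueError(f"missing variable configs: {sorted(missing)}")

    def with_overrides(self, **variables: TruncatedNormal) -> "CohortConfig":
        merged = dict(self.variables)
        merged.update(variables)
        return replace(self, variables=merged)


@dataclass(frozen=True)
class HipRecord:
    hip_id: str
    side: str
    orientation: ComponentOrientation
    pose_max_flexion: HipPose
    pose_max_extension: HipPose


@dataclass(frozen=True)
class Cohort:
    """Generated or loaded per-hip records."""

    hips: tuple[HipRecord, ...]

    def __len__(self) -> int:
        return len(self.hips)

    def __iter__(self):
        return iter(self.hips)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for h in self.hips:
            rows.append(
                {
                    "hip_id": h.hip_id,
                    "side": h.side,
                    "cup_inclination_deg": h.orientation.cup_inclination,
                    "cup_anteversion_deg": h.orientation.cup_anteversion,
                    "stem_anteversion_deg": h.orientation.stem_anteversion,
                    "flex_maxflex_deg": h.pose_max_flexion.flexion,
                    "addabd_maxflex_deg": h.pose_max_flexion.adduction,
                    "rot_maxflex_deg": h.pose_max_flexion.internal_rotation,
                    "flex_maxext_deg": h.pose_max_extension.flexion,
                    "addabd_maxext_deg": h.pose_max_extension.adduction,
                    "rot_maxext_deg": h.pose_max_extension.internal_rotation,
                }
            )
        return pd.DataFrame(rows)


COHORT_COLUMNS = [
    "hip_id",
    "side",
    "cup_inclination_deg",
    "cup_anteversion_deg",
    "stem_anteversion_deg",
    "flex_maxflex_deg",
    "addabd_maxflex_deg",
    "rot_maxflex_deg",
    "flex_maxext_deg",
    "addabd_maxext_deg",
    "rot_maxext_deg",
]

#: addabd columns carry the published abduction-positive sign in the
#: ``table2`` CSV dialect and adduction-positive internally.
_ADDABD_COLUMNS = ["addabd_maxflex_deg", "addabd_maxext_deg"]


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Draw a seeded cohort of per-hip records.

    Cup and stem anteversion are sampled jointly: a bivariate standard normal
    with correlation ``ca_correlation`` is mapped through the normal CDF and
    the per-variable truncated-normal quantile functions (Gaussian copula).
    All other variables are independent inverse-CDF draws.  The draw order is
    fixed, so a given seed yields the same cohort on any platform.
    """
    if config is None:
        config = CohortConfig()
    if config.variables.get(_INCONSISTENT_DEFAULT) == DEFAULT_VARIABLES[_INCONSISTENT_DEFAULT]:
        warnings.warn(
            "max-extension adduction/abduction defaults derive from a published "
            "row whose mean lies outside its printed range; the range has been "
            "widened to (-10.7, 4.5) adduction-positive to cover the mean",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    n = config.n
    rho = config.ca_correlation

    # Correlated cup/stem anteversion via Gaussian copula.
    z = rng.standard_normal((n, 2))
    z2 = rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1]
    u_cup = norm.cdf(z[:, 0])
    u_stem = norm.cdf(z2)
    draws: dict[str, np.ndarray] = {
        "cup_anteversion": config.variables["cup_anteversion"].ppf(u_cup),
        "stem_anteversion": config.variables["stem_anteversion"].ppf(u_stem),
    }
    for name in _VARIABLE_ORDER:
        if name in draws:
            continue
        draws[name] = config.variables[name].ppf(rng.random(n))

    hips = []
    for i in range(n):
        hips.append(
            HipRecord(
                hip_id=f"H{i + 1:03d}",
                side="right",
                orientation=ComponentOrientation(
                    cup_inclination=float(draws["cup_inclination"][i]),
                    cup_anteversion=float(draws["cup_anteversion"][i]),
                    stem_anteversion=float(draws["stem_anteversion"][i]),
                    side="right",
                ),
                pose_max_flexion=HipPose(
                    flexion=float(draws["flex_maxflex"][i]),
                    adduction=float(draws["add_maxflex"][i]),
                    internal_rotation=float(draws["rot_maxflex"][i]),
                ),
                pose_max_extension=HipPose(
                    flexion=float(draws["flex_maxext"][i]),
                    adduction=float(draws["add_maxext"][i]),
                    internal_rotation=float(draws["rot_maxext"][i]),
                ),
            )
        )
    return Cohort(hips=tuple(hips))


def cohort_summary(cohort: Cohort) -> pd.DataFrame:
    """Per-variable mean, SD, min, max in the published table layout.

    SD is the sample standard deviation (ddof=1); a single-hip cohort reports
    SD 0.  The ``summary`` column formats each row as ``mean ± SD (min–max)``.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    frame = cohort.to_frame()
    rows = []
    for col in COHORT_COLUMNS[2:]:
        x = frame[col].to_numpy(dtype=float)
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        lo, hi = float(np.min(x)), float(np.max(x))
        rows.append(
            {
                "variable": col,
                "mean": mean,
                "sd": sd,
                "min": lo,
                "max": hi,
                "summary": f"{mean:.1f} ± {sd:.1f} ({lo:.1f}–{hi:.1f})",
            }
        )
    return pd.DataFrame(rows)


def write_cohort_csv(cohort: Cohort, path, sign_dialect: str = "internal") -> None:
    """Write the cohort CSV schema; first line records the sign dialect.

    ``internal`` keeps adduction-positive addabd columns; ``table2`` writes
    the published abduction-positive sign (columns negated).
    """
    frame = cohort.to_frame()[COHORT_COLUMNS].copy()
    if sign_dialect == "table2":
        for col in _ADDABD_COLUMNS:
            frame[col] = -frame[col]
    elif sign_dialect != "internal":
        raise ValueError(f"sign_dialect must be 'internal' or 'table2', got {sign_dialect!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sign_dialect: {sign_dialect}\n")
        frame.to_csv(fh, index=False)


def read_cohort_csv(path, sign_dialect: str | None = None) -> Cohort:
    """Read the cohort CSV schema, honoring the sign-dialect header flag.

    An explicit ``sign_dialect`` argument overrides the header; files without
    a header flag default to ``internal``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            file_dialect = first.split(":", 1)[1].strip() if ":" in first else "internal"
        else:
            file_dialect = "internal"
            fh.seek(0)
        frame = pd.read_csv(fh)
    dialect = sign_dialect if sign_dialect is not None else file_dialect
    if dialect not in ("internal", "table2"):
        raise ValueError(f"unknown sign_dialect {dialect!r}")
    missing = set(COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    if dialect == "table2":
        for col in _ADDABD_COLUMNS:
            frame[col] = -frame[col]
    hips = []
    for _, row in frame.iterrows():
        hips.append(
            HipRecord(
                hip_id=str(row["hip_id"]),
                side=str(row["side"]),
                orientation=ComponentOrientation(
                    cup_inclination=float(row["cup_inclination_deg"]),
                    cup_anteversion=float(row["cup_anteversion_deg"]),
                    stem_anteversion=float(row["stem_anteversion_deg"]),
                    side=str(row["side"]),
                ),
                pose_max_flexion=HipPose(
                    flexion=float(row["flex_maxflex_deg"]),
                    adduction=float(row["addabd_maxflex_deg"]),
                    internal_rotation=float(row["rot_maxflex_deg"]),
                ),
                pose_max_extension=HipPose(
                    flexion=float(row["flex_maxext_deg"]),
                    adduction=float(row["addabd_maxext_deg"]),
                    internal_rotation=float(row["rot_maxext_deg"]),
                ),
            )
        )
    return Cohort(hips=tuple(hips))
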