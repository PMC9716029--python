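"""Pipeline orchestration: generate/load → sweep → analyze → report.

A run is reproducible from its configuration and seed alone; every stage
writes plain CSV/JSON and the manifest records the config echo, seed,
package version, and per-stage row counts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clearance import liner_neck_distance  # noqa: F401  (re-exported for drivers)
from .cohort import (
    Cohort,
    CohortConfig,
    TruncatedNormal,
    cohort_summary,
    generate_cohort,
    read_cohort_csv,
    write_cohort_csv,
)
from .implant import DEFAULT_IMPLANT, ImplantSpec, make_implant_spec
from .sweep import POSTURES, CohortSweepResult, SweepGrid, cohort_sweep
from .stats import compare_groups, roc_cutoff, safe_zone

__all__ = [
    "RunConfig",
    "run_pipeline",
    "analyze_cohort",
    "PARAMETERS",
    "ANALYSIS_CELLS",
]

log = logging.getLogger("thasim")

#: Orientation parameters entering the ROC / group-comparison stage.
PARAMETERS = (
    "cup_inclination",
    "cup_anteversion",
    "stem_anteversion",
    "combined_anteversion",
)

#: (rotation, adduction) cells at which impingement groups are formed:
#: 45° rotation with 20° adduction and 60° rotation without adduction.
ANALYSIS_CELLS = ((45.0, 20.0), (60.0, 0.0))

_SAFE_ZONE_PARAMS = ("cup_anteversion", "stem_anteversion", "combined_anteversion")


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable run description."""

    implant: ImplantSpec = DEFAULT_IMPLANT
    cohort_file: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    grids: dict[str, SweepGrid] = field(
        default_factory=lambda: {p: SweepGrid(posture=p) for p in POSTURES}
    )
    rounding: str = "nearest"
    out_dir: str = "results"

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, cohort=replace(self.cohort, seed=seed))

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"unreadable config: expected a mapping in {path}")
        implant = DEFAULT_IMPLANT
        if "implant" in raw:
            b = raw["implant"]
            implant = make_implant_spec(
                b.get("head_diameter_mm", 32.0),
                b.get("neck_diameter_mm", 9.0),
                b.get("neck_shaft_angle_deg", 130.0),
                b.get("neck_length_mm", 40.0),
            )
        cohort_cfg = CohortConfig()
        if "cohort" in raw:
            b = dict(raw["cohort"])
            overrides = {
                name: TruncatedNormal(**params)
                for name, params in b.pop("variables", {}).items()
            }
            cohort_cfg = CohortConfig(
                n=b.get("n", 32),
                seed=b.get("seed", 0),
                ca_correlation=b.get("ca_correlation", -0.3),
            ).with_overrides(**overrides)
        grids = {p: SweepGrid(posture=p) for p in POSTURES}
        if "grids" in raw:
            for posture, g in raw["grids"].items():
                grids[posture] = SweepGrid(
                    rotation_values=tuple(g.get("rotation_values", SweepGrid().rotation_values)),
                    addabd_values=tuple(g.get("addabd_values", SweepGrid().addabd_values)),
                    posture=posture,
                )
        return RunConfig(
            implant=implant,
            cohort_file=raw.get("cohort_file"),
            cohort=cohort_cfg,
            grids=grids,
            rounding=raw.get("analysis", {}).get("rounding", "nearest"),
            out_dir=raw.get("out_dir", "results"),
        )

    def to_dict(self) -> dict:
        return {
            "implant": {
                "head_diameter_mm": self.implant.head_diameter,
                "neck_diameter_mm": self.implant.neck_diameter,
                "neck_shaft_angle_deg": self.implant.neck_shaft_angle,
                "neck_length_mm": self.implant.neck_length,
                "liner_type": self.implant.liner_type,
            },
            "cohort_file": self.cohort_file,
            "cohort": {
                "n": self.cohort.n,
                "seed": self.cohort.seed,
                "ca_correlation": self.cohort.ca_correlation,
                "variables": {
                    k: {"mean": v.mean, "sd": v.sd, "lower": v.lower, "upper": v.upper}
                    for k, v in self.cohort.variables.items()
                },
            },
            "grids": {
                p: {
                    "rotation_values": list(g.rotation_values),
                    "addabd_values": list(g.addabd_values),
                }
                for p, g in self.grids.items()
            },
            "analysis": {"rounding": self.rounding},
            "out_dir": self.out_dir,
        }


def analyze_cohort(
    cohort: Cohort,
    sweeps: CohortSweepResult,
    rounding: str = "nearest",
    cells=ANALYSIS_CELLS,
) -> dict:
    """ROC cutoffs, group comparisons, and safe zones from cohort sweeps.

    Anterior impingement (maximum flexion, internal rotation) is modeled as
    *case if the parameter is below* its cutoff; posterior impingement
    (maximum extension, external rotation) as *case if above*.  The safe zone
    combines the anterior and posterior cutoffs of the 45°-rotation,
    20°-adduction cell for cup anteversion, stem anteversion and combined
    anteversion.
    """
    frame = cohort.to_frame()
    values = {
        "cup_inclination": frame["cup_inclination_deg"].to_numpy(),
        "cup_anteversion": frame["cup_anteversion_deg"].to_numpy(),
        "stem_anteversion": frame["stem_anteversion_deg"].to_numpy(),
        "combined_anteversion": (
            frame["cup_anteversion_deg"] + frame["stem_anteversion_deg"]
        ).to_numpy(),
    }
    conditions = [
        ("anterior", "max_flexion", "case_if_below"),
        ("posterior", "max_extension", "case_if_above"),
    ]
    roc_rows, cmp_rows = [], []
    cutoffs: dict[tuple[str, tuple[float, float]], dict[str, float]] = {}
    for name, posture, direction in conditions:
        for cell in cells:
            rot, add = cell
            mask = sweeps.impinged_at(posture, rot, add)
            per_param: dict[str, float] = {}
            for param in PARAMETERS:
                x = values[param]
                row = {
                    "condition": name,
                    "rotation_deg": rot,
                    "addabd_deg": add,
                    "parameter": param,
                    "n_impinged": int(mask.sum()),
                    "n_total": len(mask),
                }
                if mask.all() or not mask.any():
                    roc_rows.append(
                        {**row, "auc": np.nan, "cutoff": np.nan,
                         "sensitivity": np.nan, "specificity": np.nan,
                         "note": "single class"}
                    )
                    continue
                r = roc_cutoff(x, mask, direction)
                per_param[param] = r.cutoff
                roc_rows.append(
                    {**row, "auc": r.auc, "cutoff": r.cutoff,
                     "sensitivity": r.sensitivity, "specificity": r.specificity,
                     "note": ""}
                )
                stat, p, test = compare_groups(x[mask], x[~mask], "normal")
                cmp_rows.append(
                    {**row, "mean_impinged": float(x[mask].mean()),
                     "mean_non_impinged": float(x[~mask].mean()),
                     "statistic": stat, "p_value": p, "test": test}
                )
            cutoffs[(name, cell)] = per_param

    primary = cells[0]
    ant = cutoffs.get(("anterior", primary), {})
    post = cutoffs.get(("posterior", primary), {})
    zone = None
    if all(p in ant and p in post for p in _SAFE_ZONE_PARAMS):
        zone = safe_zone(
            {p: ant[p] for p in _SAFE_ZONE_PARAMS},
            {p: post[p] for p in _SAFE_ZONE_PARAMS},
            rounding=rounding,
        )
    inclination_cutoffs = {
        "anterior": ant.get("cup_inclination"),
        "posterior": post.get("cup_inclination"),
    }
    return {
        "roc": pd.DataFrame(roc_rows),
        "comparisons": pd.DataFrame(cmp_rows),
        "safe_zone": zone,
        "cup_inclination_cutoffs": inclination_cutoffs,
        "cell": primary,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write run artifacts to ``config.out_dir``.

    Returns a manifest dict (also written as ``manifest.json``).
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "seed": config.cohort.seed,
        "version": __version__,
        "files": {},
    }

    if config.cohort_file:
        log.info("loading cohort from %s", config.cohort_file)
        cohort = read_cohort_csv(config.cohort_file)
    else:
        log.info("generating cohort: n=%d seed=%d", config.cohort.n, config.cohort.seed)
        cohort = generate_cohort(config.cohort)
    cohort_path = out / "cohort.csv"
    write_cohort_csv(cohort, cohort_path)
    manifest["files"]["cohort.csv"] = {"rows": len(cohort)}
    summary = cohort_summary(cohort)
    summary.to_csv(out / "cohort_summary.csv", index=False)
    manifest["files"]["cohort_summary.csv"] = {"rows": len(summary)}

    log.info("sweeping %d hips over %d postures", len(cohort), len(config.grids))
    sweeps = cohort_sweep(config.implant, cohort, config.grids)
    long = sweeps.long_table()
    for posture in config.grids:
        sub = long[long.posture == posture]
        name = f"sweeps_{posture.removeprefix('max_')}.csv"
        sub.to_csv(out / name, index=False)
        manifest["files"][name] = {"rows": len(sub)}
    rates = pd.concat([sweeps.rates(p) for p in config.grids], ignore_index=True)
    rates.to_csv(out / "rates.csv", index=False)
    manifest["files"]["rates.csv"] = {"rows": len(rates)}

    log.info("analyzing impingement groups")
    analysis = analyze_cohort(cohort, sweeps, rounding=config.rounding)
    analysis["roc"].to_csv(out / "roc.csv", index=False)
    manifest["files"]["roc.csv"] = {"rows": len(analysis["roc"])}
    analysis["comparisons"].to_csv(out / "comparisons.csv", index=False)
    manifest["files"]["comparisons.csv"] = {"rows": len(analysis["comparisons"])}

    zone = analysis["safe_zone"]
    zone_payload = {
        "cell": {"rotation_deg": analysis["cell"][0], "addabd_deg": analysis["cell"][1]},
        "rounding": config.rounding,
        "intervals": None if zone is None else {
            k: (None if v is None else list(v)) for k, v in zone.intervals.items()
        },
        "cup_inclination_cutoffs": analysis["cup_inclination_cutoffs"],
    }
    with open(out / "safezone.json", "w", encoding="utf-8") as fh:
        json.dump(zone_payload, fh, indent=2)
    manifest["files"]["safezone.json"] = {"rows": 1}

    manifest["postures"] = list(config.grids)
    manifest["cells_per_posture"] = {
        p: len(g.rotation_values) * len(g.addabd_values) for p, g in config.grids.items()
    }
    manifest["elapsed_s"] = round(time.time() - t0, 3)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    log.info("pipeline finished in %.2fs", manifest["elapsed_s"])
    return manifest
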