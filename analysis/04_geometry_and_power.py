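"""Design checks: closed-form implant geometry against the sampling oracle,
per-hip safe rotation margins, and the two-group power computation behind
the 32-hip cohort size.

Reads results/cohort.csv; writes results/geometry_power.json.
"""

import argparse
import json
import math
from pathlib import Path

import numpy as np

from thasim import (
    DEFAULT_IMPLANT,
    make_implant_spec,
    oscillation_angle,
    oscillation_angle_by_sweep,
    read_cohort_csv,
    rotation_to_impingement,
    sample_size_two_group,
)


def main() -> None:
    p = argparse.ArgumentParser()
    p.add_argument("--out", type=Path, default=Path("results"))
    args = p.parse_args()

    spec = DEFAULT_IMPLANT
    closed = oscillation_angle(spec)
    swept = oscillation_angle_by_sweep(spec)
    print(f"oscillation angle (32/9 mm): closed form {closed:.2f} deg, "
          f"contact sweep {swept:.2f} deg")
    alt = make_implant_spec(28, 9, 130)
    print(f"  28 mm head comparison: {oscillation_angle(alt):.2f} deg "
          "(smaller head-neck ratio narrows the arc)")

    n_total = sample_size_two_group(14, 14, 0.05, 0.80)
    print(f"two-group design (14 deg CA difference, SD 14, alpha 5%, power 80%): "
          f"{n_total} hips")

    cohort = read_cohort_csv(args.out / "cohort.csv")
    margins = {"max_flexion": [], "max_extension": []}
    for hip in cohort:
        for posture, pose in [
            ("max_flexion", hip.pose_max_flexion),
            ("max_extension", hip.pose_max_extension),
        ]:
            margins[posture].append(
                rotation_to_impingement(spec, hip.orientation, pose, 20.0, posture)
            )
    stats = {}
    for posture, vals in margins.items():
        finite = [v for v in vals if math.isfinite(v)]
        stats[posture] = {
            "median_safe_rotation_deg": float(np.median(vals)) if finite else None,
            "min_safe_rotation_deg": float(np.min(vals)),
            "n_unreachable": int(sum(math.isinf(v) for v in vals)),
        }
        kind = "internal" if posture == "max_flexion" else "external"
        print(
            f"{posture}: median safe {kind} rotation at 20 deg adduction "
            f"{np.median(vals):.1f} deg (min {np.min(vals):.1f})"
        )

    payload = {
        "oscillation_angle_closed_deg": closed,
        "oscillation_angle_sweep_deg": swept,
        "sample_size_total": n_total,
        "safe_rotation_at_20_adduction": stats,
    }
    (args.out / "geometry_power.json").write_text(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
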