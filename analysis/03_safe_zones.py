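"""Statistical stage: distance-rotation correlations, impingement-group
comparisons, ROC cutoffs, and the combined safe zones.

Reads results/cohort.csv and the sweep tables (run 01 and 02 first); writes
results/roc.csv, results/comparisons.csv, results/correlations.csv and
results/safezone.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from thasim import DEFAULT_IMPLANT, analyze_cohort, cohort_sweep, pearson, read_cohort_csv


def main() -> None:
    p = argparse.ArgumentParser()
    p.add_argument("--out", type=Path, default=Path("results"))
    p.add_argument("--rounding", choices=["nearest", "inward"], default="nearest")
    args = p.parse_args()

    cohort = read_cohort_csv(args.out / "cohort.csv")
    sweeps = cohort_sweep(DEFAULT_IMPLANT, cohort)
    long = sweeps.long_table()

    # Distance vs simulated rotation, pooled over hips, at zero adduction.
    corr_rows = []
    for posture in ("max_flexion", "max_extension"):
        sub = long[(long.posture == posture) & (long.addabd_deg == 0.0)]
        r, pval = pearson(sub.rotation_deg, sub.distance_mm)
        corr_rows.append(
            {"posture": posture, "r": r, "p_value": pval, "n_points": len(sub)}
        )
        print(f"{posture}: distance vs rotation r = {r:.2f} (p = {pval:.2e})")
    pd.DataFrame(corr_rows).to_csv(args.out / "correlations.csv", index=False)

    res = analyze_cohort(cohort, sweeps, rounding=args.rounding)
    res["roc"].to_csv(args.out / "roc.csv", index=False)
    res["comparisons"].to_csv(args.out / "comparisons.csv", index=False)

    print("\nROC cutoffs (45 deg rotation, 20 deg adduction):")
    roc45 = res["roc"].query("rotation_deg == 45 and addabd_deg == 20")
    print(
        roc45[["condition", "parameter", "auc", "cutoff"]]
        .round(2)
        .to_string(index=False)
    )

    zone = res["safe_zone"]
    payload = {
        "rounding": args.rounding,
        "intervals": None
        if zone is None
        else {k: (None if v is None else list(v)) for k, v in zone.intervals.items()},
        "cup_inclination_cutoffs": res["cup_inclination_cutoffs"],
    }
    (args.out / "safezone.json").write_text(json.dumps(payload, indent=2))
    print("\nsafe zones (no anterior nor posterior impingement at 45/20):")
    if zone is None:
        print("  not estimable (single-class cell)")
    else:
        for k, v in zone.intervals.items():
            print(f"  {k}: {'empty' if v is None else f'{v[0]}–{v[1]} deg'}")


if __name__ == "__main__":
    main()
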