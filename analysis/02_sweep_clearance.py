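"""Sweep every hip through the virtual rotation x adduction grids at its
actual maximum flexion and extension, and tabulate liner-to-neck distances
and impingement rates.

Reads results/cohort.csv (run 01_generate_cohort.py first); writes
results/sweeps_flexion.csv, results/sweeps_extension.csv and
results/rates.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from thasim import DEFAULT_IMPLANT, cohort_sweep, read_cohort_csv


def main() -> None:
    p = argparse.ArgumentParser()
    p.add_argument("--out", type=Path, default=Path("results"))
    args = p.parse_args()

    cohort = read_cohort_csv(args.out / "cohort.csv")
    result = cohort_sweep(DEFAULT_IMPLANT, cohort)

    long = result.long_table()
    for posture, name in [
        ("max_flexion", "sweeps_flexion.csv"),
        ("max_extension", "sweeps_extension.csv"),
    ]:
        long[long.posture == posture].to_csv(args.out / name, index=False)
    rates = pd.concat(
        [result.rates(p) for p in ("max_flexion", "max_extension")], ignore_index=True
    )
    rates.to_csv(args.out / "rates.csv", index=False)

    print(f"swept {len(cohort)} hips x 2 postures x 25 cells")
    for posture, label in [
        ("max_flexion", "anterior (max flexion, internal rotation)"),
        ("max_extension", "posterior (max extension, external rotation)"),
    ]:
        print(f"\n{label}: mean liner-to-neck distance (mm)")
        mean = (
            long[long.posture == posture]
            .pivot_table(index="rotation_deg", columns="addabd_deg", values="distance_mm")
            .round(2)
        )
        print(mean)
    for rot, add in [(45.0, 20.0), (60.0, 0.0)]:
        ant = result.impinged_at("max_flexion", rot, add).mean()
        post = result.impinged_at("max_extension", rot, add).mean()
        print(
            f"\nimpingement at {rot:.0f} deg rotation, {add:.0f} deg adduction: "
            f"anterior {ant:.0%}, posterior {post:.0%}"
        )


if __name__ == "__main__":
    main()
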