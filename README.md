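# thasim

Simulation of prosthetic **liner-to-neck impingement** after total hip
arthroplasty (THA), for biomechanics researchers and arthroplasty surgeons
studying component-orientation "safe zones".

During deep flexion (squatting) or extension, an unintentional internal or
external rotation — especially with adduction — can drive the stem neck
against the polyethylene liner rim. `thasim` models the prosthesis as a
32 mm head in a flat hemispherical liner with a 9 mm cylindrical neck
(head-neck ratio 3.56, neck-shaft angle 130°), expresses the neck axis in
the liner frame from radiographic cup inclination/anteversion (RI, RA),
stem anteversion (α) and Cardan x-y-z hip angles
(flexion → adduction → rotation), and evaluates the clearance

    d(θ) = max(R·cos θ − r, 0)

where θ is the neck's polar angle in the liner frame, `R` the head radius
and `r` the neck radius; contact occurs at θ ≥ 90° − arcsin(r/R) — half the
oscillation angle 180° − 2·arcsin(r/R). On a seeded synthetic cohort that
emulates a published 32-hip squatting study (truncated-normal component
orientations and poses, negatively correlated cup/stem anteversion from the
combined-anteversion technique), it sweeps virtual rotation (0–60°) ×
adduction (−20–20°) grids at each hip's actual maximum flexion/extension,
then derives impingement rates, ROC (Youden) cutoffs, and the safe-zone
intervals of cup anteversion, stem anteversion, and combined anteversion
(CA = cup + stem).

## Worked example

```python
import numpy as np
from thasim import (DEFAULT_IMPLANT, ComponentOrientation, HipPose,
                    neck_axis_in_liner, liner_neck_distance,
                    oscillation_angle)

spec = DEFAULT_IMPLANT                       # 32 mm head, 9 mm neck, 130°
print(round(spec.head_neck_ratio, 2))        # 3.56
print(round(oscillation_angle(spec), 1))     # 147.3  (degrees of free travel)

hip = ComponentOrientation(cup_inclination=38, cup_anteversion=16,
                           stem_anteversion=34)
squat = HipPose(flexion=81, adduction=20, internal_rotation=45)
d = neck_axis_in_liner(spec, hip, squat)
print(liner_neck_distance(spec, d))
# ClearanceResult(min_distance=3.92..., impinged=False,
#                 contact_side='anterior', neck_polar_angle=58.5...)
```

A typically oriented hip keeps ~3.9 mm of anterior clearance even at 45°
internal rotation with 20° adduction in deep flexion; the same hip at
maximum *extension* with 45° external rotation and 20° adduction impinges
posteriorly (distance 0), which is why posterior impingement dominates in
the cohort experiment below.

## Cohort analysis

The numbered drivers reproduce the full study pipeline on the synthetic
cohort (run from the repository root; outputs land in `results/`):

```sh
python analysis/01_generate_cohort.py        # cohort.csv + summary vs targets
python analysis/02_sweep_clearance.py        # distance surfaces, rates
python analysis/03_safe_zones.py             # correlations, ROC, safe zones
python analysis/04_geometry_and_power.py     # oracle checks, safety margins
```

With the default 32-hip cohort (seed 0) this prints, among other things:

```
impingement at 45 deg rotation, 20 deg adduction: anterior 6%, posterior 69%
max_flexion: distance vs rotation r = -0.80 (p = 6.95e-37)
safe zones (no anterior nor posterior impingement at 45/20):
  cup_anteversion: 14–14 deg
  stem_anteversion: 30–40 deg
  combined_anteversion: 39–53 deg
```

i.e. clearances shrink monotonically with rotation and adduction, posterior
impingement at maximum extension is far more frequent than anterior
impingement at maximum flexion, and the impingement-free window of combined
anteversion spans roughly 40–55°. Exact rates and cutoffs vary with the
cohort draw, since they depend on 32-hip sampling noise.

The same pipeline is available as a CLI (`thasim run | generate-cohort |
sweep | analyze`) and programmatically via `thasim.run_pipeline`.

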