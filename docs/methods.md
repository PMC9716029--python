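# Methods

## Problem and model

After total hip arthroplasty (THA), contact between the polyethylene liner
rim and the prosthetic stem neck ("liner-to-neck impingement") at the
extremes of motion is a risk factor for dislocation, rim wear, and liner
fracture. This package simulates that mechanism for a squatting motion: it
places a parametric prosthesis according to per-hip component orientations,
drives the hip through virtual rotation and adduction excursions at the
measured extremes of flexion and extension, and asks when and on which side
the neck reaches the liner rim.

The prosthesis is an idealized ball-and-socket:

* **Head / liner.** A spherical head of diameter 32 mm seated concentrically
  in a *flat* hemispherical liner of equal inner radius. The liner rim is
  the circle of radius `R = 16 mm` in the equatorial plane through the head
  center. Liner thickness, chamfers and the outer shell are ignored — for a
  neck inside the opening cone the rim is always the closest liner feature.
* **Neck.** A cylinder of diameter 9 mm emanating from the head center along
  the neck axis, truncated at 40 mm. No taper, skirt or trunnion flare is
  modeled; the published implant is characterized only by its head-neck
  ratio 32/9 = 3.56 and its 130° neck-shaft angle.

With unit neck direction at polar angle θ from the liner axis, the minimum
rim-to-neck distance has the closed form

    d(θ) = max(R·cos θ − r, 0),          r = neck radius,

with contact exactly at `θ* = 90° − arcsin(r/R)` (73.65° for 32/9 mm), half
the oscillation angle `180° − 2·arcsin(r/R)`. Both formulas are verified in
the test suite against independent brute-force sampling oracles (grids of
rim and neck-surface points; a 0.01° contact sweep for the oscillation
angle) to 0.05 mm and 0.1° respectively.

## Frames and conventions

* **Pelvis frame** = anterior pelvic plane frame: +x toward the patient's
  right, +y anterior, +z superior. The pelvis is held fixed; measured poses
  are interpreted as hip angles relative to this frame (the source
  kinematics embed pelvic motion in the measured hip angles, and no separate
  pelvic-tilt series is available).
* **Cup orientation** uses the radiographic (Murray) definitions.  The cup
  opening axis for a right hip is
  `n = (sin RI·cos RA, sin RA, −cos RI·cos RA)`; left hips mirror x.  The
  liner frame takes `n` as its z-axis and the rim-plane projection of the
  pelvis anterior axis as its x-axis, which fixes the azimuth origin for
  anterior/posterior contact labeling (a nearest rim point is "anterior"
  when its pelvis-frame anterior component is positive; in liner
  coordinates this reduces to the sign of the neck direction's first
  component).
* **Stem.** The stem is assumed perfectly aligned with the femoral shaft
  (+z); stem anteversion α rotates the neck about the shaft relative to the
  posterior condylar line. The head-to-shaft neck direction for a right hip
  is `−(−sin(180°−γ)·cos α, sin(180°−γ)·sin α, cos(180°−γ))` with γ the
  neck-shaft angle.
* **Hip pose.** Intrinsic Cardan rotations in x-y-z order:
  `R = Rx(flexion)·Ry(s·adduction)·Rz(s·internal rotation)`, `s = ±1` for
  right/left, so the same (side-neutral) angle signs describe the same
  physical motion on either side. `Rx` is the standard right-handed
  rotation, so 90° flexion carries the distal femur (−z) to anterior (+y).
  The source kinematics state the x-y-z order but not intrinsic vs.
  extrinsic composition; intrinsic (body-fixed) composition is the standard
  joint-angle convention and is fixed here. Mirror symmetry (left hip =
  x-mirror of the right hip at identical pose angles, identical clearance)
  is enforced by a property test.

## Virtual sweeps

For each hip and posture (maximum flexion, maximum extension) the measured
flexion is retained while adduction and rotation are **replaced** by grid
values: rotations 0–60° in 15° steps (internal at max flexion, external at
max extension) × adduction −20–20° in 10° steps (adduction positive).
Replacement rather than offset is assumed because the published grids start
at 0° while the measured poses have nonzero rotation; a property test pins
the replacement semantics. A continuous variant (`rotation_to_impingement`)
bisects the rotation magnitude to 0.01° for per-hip safety margins.

## Synthetic cohort

The study's raw 32-hip records are not public. The generator draws each
variable from a truncated normal matching the published mean ± SD (range)
(component orientations: cup inclination 38.1 ± 5.8 (27–48), cup anteversion
16.4 ± 6.0 (4–32), stem anteversion 33.6 ± 11.4 (7–60); squatting poses at
both extremes likewise). Published pose rows use abduction-positive signs
and are negated internally; the CSV reader/writer supports both dialects
via a header flag. Draws are inverse-CDF transforms of a seeded
`numpy.random.default_rng` stream with a fixed draw order, so cohorts are
bit-reproducible across platforms.

Cup and stem anteversion are drawn jointly through a Gaussian copula with
correlation −0.3, emulating the combined-anteversion surgical technique
(cup anteversion adjusted against the measured stem anteversion toward a
40–60° sum) without hard clipping. The true joint distribution is unknown;
−0.3 concentrates combined anteversion near 50° while keeping realistic
tails. Note a side effect: the negative correlation weakens the *marginal*
association between cup anteversion and impingement relative to the real
cohort, so cup-anteversion group differences are small (≈2°) and can flip
sign in a single 32-hip draw, while stem and combined anteversion effects
are large and stable.

Known deviations from real data: all hips are right-sided (sides are exact
mirrors for this geometry), variables other than the anteversion pair are
mutually independent, bilateral hips are uncorrelated, and no
bone-on-bone, soft-tissue or elevated-rim effects exist. Passing tests
therefore demonstrate the geometry, conventions, and statistical machinery
— and the *directions* of the cohort-level findings — not the exact
published rates, which depend on the unavailable per-hip records. One
published pose row (max-extension adduction/abduction, 3.6 ± 3.1 with range
−4.5–1.4 abduction-positive) is internally inconsistent (mean outside
range); the default widens the range to cover the mean and the generator
warns when that default is used.

## Statistics

* **Correlations**: Pearson r with two-sided p (t transform).
* **Group comparisons**: pooled-variance Student t or Wilcoxon rank-sum
  (normal approximation), caller-selected; no multiplicity correction.
* **ROC cutoffs**: empirical ROC over all observed thresholds
  (`sklearn.metrics.roc_curve` with `drop_intermediate=False`), cutoff at
  the observed score maximizing Youden's J; ties resolved toward the cutoff
  admitting the larger impingement-free zone; AUC by trapezoid. Anterior
  impingement is modeled as case-if-below (low anteversion impinges
  anteriorly), posterior as case-if-above.
* **Safe zones**: per parameter, the interval between the anterior and
  posterior cutoffs at the 45°-rotation / 20°-adduction cell, integerized
  by nearest-integer (half-up) rounding by default; a conservative
  ceil/floor "inward" mode is available. Crossed cutoffs yield an
  explicitly empty zone.
* **Sample size**: per-group `n = ceil(2·(z₁₋α/₂ + z_power)²·(sd/δ)²)`,
  total = 2n (normal approximation, two-sided).

## Numerical choices

* Clearance boundary (distance exactly 0) counts as impinged.
* The brute-force distance oracle samples coarse global grids (2° rim, 4°
  cylinder azimuth, 0.5 mm axial) and refines a ±2-cell window at 0.05°/
  0.05 mm; agreement with the closed form is asserted to 0.05 mm.
* The contact-sweep oscillation oracle steps 0.01° after a 1° bracketing
  pass (detection identical to a full fine sweep); sampling granularities
  bound its bias below 0.1°.
* Rotation matrices are validated to 1e−9 orthonormality; gimbal
  degeneracy (|adduction| = 90°, far outside physiologic squatting range)
  raises an error.
* Bisection for `rotation_to_impingement` terminates at 0.01° and returns
  `inf` when no rotation up to 120° impinges.

## Problem sizes

The shipped analysis uses the study-sized cohort (n = 32, seed 0) for the
sweeps and statistics, n = 10,000 for generator calibration, 100 random
directions for the clearance-oracle comparison, and 200 random instances
for the ROC brute-force cross-check.

## Limitations

Single implant family (flat liner, fixed neck geometry); no elevated-rim
liners, dual mobility, bone or soft-tissue impingement, micro-separation,
pelvic-tilt dynamics, or measurement error; the azimuth convention for
anterior/posterior labeling is the simplest one consistent with a
projection of the anterior axis, the source's exact convention being
unstated.
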