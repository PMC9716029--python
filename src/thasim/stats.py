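"""Statistical stage: correlations, group comparisons, ROC cutoffs,
safe-zone intervals, and the two-group power computation.

Cutoffs are selected on empirical ROC curves by maximizing Youden's
J = sensitivity + specificity − 1, reported at an observed score value.  A
safe zone for an orientation parameter is the integer interval between the
anterior-impingement cutoff (below which anterior impingement occurs) and
the posterior-impingement cutoff (above which posterior impingement occurs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "pearson",
    "compare_groups",
    "ROCResult",
    "roc_cutoff",
    "SafeZone",
    "safe_zone",
    "sample_size_two_group",
]

DIRECTIONS = ("case_if_below", "case_if_above")


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def compare_groups(
    a: Sequence[float], b: Sequence[float], normality: str = "normal"
) -> tuple[float, float, str]:
    """Two-sided two-group comparison.

    ``normality='normal'`` runs Student's t-test with pooled variance;
    ``'nonnormal'`` runs the Wilcoxon rank-sum test (normal approximation).
    Returns (statistic, p, test_name).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if normality == "normal":
        t, p = sps.ttest_ind(a, b, equal_var=True)
        return float(t), float(p), "student_t"
    if normality == "nonnormal":
        z, p = sps.ranksums(a, b)
        return float(z), float(p), "wilcoxon_rank_sum"
    raise ValueError(f"normality must be 'normal' or 'nonnormal', got {normality!r}")


@dataclass(frozen=True)
class ROCResult:
    auc: float
    cutoff: float
    direction: str
    sensitivity: float
    specificity: float


def roc_cutoff(
    scores: Sequence[float], case_labels: Sequence[bool], direction: str
) -> ROCResult:
    """Youden-optimal cutoff on the empirical ROC over observed thresholds.

    ``direction='case_if_below'`` classifies a case when score ≤ cutoff,
    ``'case_if_above'`` when score ≥ cutoff.  Youden ties are broken toward
    the cutoff admitting the larger non-case (safe) zone.  AUC is the
    trapezoidal area under the empirical curve.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(case_labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and case_labels must be 1-d of equal length")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    x = s if direction == "case_if_above" else -s
    fpr, tpr, thr = _sk_roc_curve(y, x, drop_intermediate=False)
    auc_val = float(_sk_auc(fpr, tpr))
    j = tpr - fpr
    # Index 0 is the "predict nothing" sentinel threshold, not an observed score.
    candidates = np.arange(1, len(thr))
    jmax = j[candidates].max()
    # Thresholds descend; the first near-tied maximizer is the largest
    # x-threshold.  In both directions that is the cutoff with the larger safe
    # zone (case_if_above: highest cutoff; case_if_below: lowest cutoff).
    # Ties are resolved within float tolerance of the count ratios.
    best = int(candidates[j[candidates] >= jmax - 1e-12][0])
    cutoff = float(thr[best]) if direction == "case_if_above" else float(-thr[best])
    return ROCResult(
        auc=auc_val,
        cutoff=cutoff,
        direction=direction,
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
    )


@dataclass(frozen=True)
class SafeZone:
    """Integer safe intervals per orientation parameter; None marks an empty zone."""

    intervals: dict[str, tuple[int, int] | None]
    rounding: str

    def is_empty(self, parameter: str) -> bool:
        return self.intervals[parameter] is None


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def safe_zone(
    anterior_cutoffs: Mapping[str, float],
    posterior_cutoffs: Mapping[str, float],
    rounding: str = "nearest",
) -> SafeZone:
    """Combine anterior (case-if-below) and posterior (case-if-above) cutoffs.

    ``rounding='nearest'`` takes the nearest integer at each endpoint
    (half-up), which reproduces conventional reporting of such ranges;
    ``'inward'`` rounds the lower endpoint up and the upper endpoint down
    (conservative interior interval).  A crossed interval yields None.
    """
    if rounding not in ("nearest", "inward"):
        raise ValueError(f"rounding must be 'nearest' or 'inward', got {rounding!r}")
    if set(anterior_cutoffs) != set(posterior_cutoffs):
        raise ValueError("anterior and posterior cutoffs must cover the same parameters")
    intervals: dict[str, tuple[int, int] | None] = {}
    for param in anterior_cutoffs:
        lo_raw = float(anterior_cutoffs[param])
        hi_raw = float(posterior_cutoffs[param])
        if rounding == "nearest":
            lo, hi = _round_half_up(lo_raw), _round_half_up(hi_raw)
        else:
            lo, hi = math.ceil(lo_raw), math.floor(hi_raw)
        intervals[param] = None if lo > hi else (int(lo), int(hi))
    return SafeZone(intervals=intervals, rounding=rounding)


def sample_size_two_group(
    delta: float, sd: float, alpha: float = 0.05, power: float = 0.80
) -> int:
    """Total n for a two-sided two-group mean comparison (normal approximation).

    Per-group ``n = ceil(2 · (z_{1−α/2} + z_power)² · (sd/δ)²)`` with a
    minimum of one per group; returns the total across both groups.
    """
    if not (delta > 0 and sd > 0):
        raise ValueError("delta and sd must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    z = sps.norm.ppf(1.0 - alpha / 2.0) + sps.norm.ppf(power)
    per_group = max(1, math.ceil(2.0 * (z * sd / delta) ** 2))
    return 2 * per_group
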