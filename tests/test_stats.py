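import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thasim import (
    compare_groups,
    pearson,
    roc_cutoff,
    safe_zone,
    sample_size_two_group,
)


def brute_youden(scores, labels, direction):
    """Independent oracle: exhaustive J maximization over observed cutoffs."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    best = None
    for c in np.unique(scores):
        pred = scores <= c if direction == "case_if_below" else scores >= c
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        j = sens + spec - 1
        # tie-break toward the larger safe zone
        better = best is None or j > best[0] + 1e-12
        tie = best is not None and abs(j - best[0]) <= 1e-12
        prefer = tie and (c < best[1] if direction == "case_if_below" else c > best[1])
        if better or prefer:
            best = (j, c, sens, spec)
    return best


class TestPearson:
    def test_perfect_anticorrelation(self):
        r, _ = pearson([1, 2, 3, 4], [-1, -2, -3, -4])
        assert r == pytest.approx(-1.0)

    def test_perfect_correlation(self):
        r, _ = pearson([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # cov=1, sd_x*sd_y computed by hand -> r = 0.6
        r, p = pearson([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6, abs=1e-12)
        assert 0 < p < 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1, 1, 1], [2, 3, 4])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [3, 4])


class TestCompareGroups:
    def test_identical_groups_rank_sum_p_one(self):
        _, p, name = compare_groups([1, 2, 3], [1, 2, 3], "nonnormal")
        assert p == pytest.approx(1.0)
        assert name == "wilcoxon_rank_sum"

    def test_identical_groups_t_zero(self):
        t, _, name = compare_groups([1, 2, 3], [1, 2, 3], "normal")
        assert t == pytest.approx(0.0)
        assert name == "student_t"

    def test_pooled_t_hand_computation(self):
        # means 12 vs 22, pooled sd 2, se 2*sqrt(2/3) -> |t| = 6.12
        t, p, _ = compare_groups([10, 12, 14], [20, 22, 24], "normal")
        assert abs(t) == pytest.approx(6.1237, abs=1e-3)
        assert p == pytest.approx(0.0036, abs=2e-4)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            compare_groups([], [1, 2])


class TestRocCutoff:
    def test_perfect_separation_below(self):
        r = roc_cutoff([10, 12, 20, 25, 30], [1, 1, 0, 0, 0], "case_if_below")
        assert r.auc == pytest.approx(1.0)
        assert r.cutoff == 12
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_perfect_separation_above(self):
        r = roc_cutoff([10, 12, 20, 25, 30], [0, 0, 0, 1, 1], "case_if_above")
        assert r.auc == pytest.approx(1.0)
        assert r.cutoff == 25

    def test_symmetric_labels_auc_half(self):
        # Cases at both extremes: P(case score > control score) = 1/2.
        r = roc_cutoff([1, 2, 3, 4], [1, 0, 0, 1], "case_if_above")
        assert r.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_cutoff([1, 2, 3], [1, 1, 1], "case_if_above")

    def test_cutoff_is_observed_score(self, rng):
        for _ in range(20):
            s = rng.normal(size=20).round(2)
            y = rng.random(20) < 0.4
            if y.all() or not y.any():
                continue
            r = roc_cutoff(s, y, "case_if_above")
            assert r.cutoff in s

    @pytest.mark.parametrize("direction", ["case_if_below", "case_if_above"])
    def test_matches_brute_force_youden(self, direction, rng):
        # 200 random small instances against the exhaustive oracle.
        for _ in range(200):
            n = rng.integers(4, 50)
            s = rng.normal(size=n).round(1)
            y = rng.random(n) < rng.uniform(0.2, 0.8)
            if y.all() or not y.any():
                continue
            j, c, sens, spec = brute_youden(s, y, direction)
            r = roc_cutoff(s, y, direction)
            assert r.sensitivity + r.specificity - 1 == pytest.approx(j, abs=1e-12)
            assert r.cutoff == pytest.approx(c)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=25)
        y = rng.random(25) < 0.5
        if y.all() or not y.any():
            return
        a1 = roc_cutoff(s, y, "case_if_above").auc
        a2 = roc_cutoff(np.exp(s / 3), y, "case_if_above").auc
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestSafeZone:
    def test_nearest_rounding_reproduces_published_ranges(self):
        z = safe_zone(
            {"cup_anteversion": 14.5, "stem_anteversion": 18.6, "combined_anteversion": 41.3},
            {"cup_anteversion": 17.6, "stem_anteversion": 34.0, "combined_anteversion": 56.2},
        )
        assert z.intervals == {
            "cup_anteversion": (15, 18),
            "stem_anteversion": (19, 34),
            "combined_anteversion": (41, 56),
        }

    def test_inward_rounding(self):
        z = safe_zone({"a": 14.5}, {"a": 17.6}, rounding="inward")
        assert z.intervals["a"] == (15, 17)
        z2 = safe_zone({"a": 41.3}, {"a": 56.2}, rounding="inward")
        assert z2.intervals["a"] == (42, 56)

    def test_crossed_cutoffs_give_empty_zone(self):
        z = safe_zone({"a": 30.0}, {"a": 20.0})
        assert z.intervals["a"] is None
        assert z.is_empty("a")

    def test_mismatched_parameters_rejected(self):
        with pytest.raises(ValueError, match="parameters"):
            safe_zone({"a": 1.0}, {"b": 2.0})


class TestSampleSize:
    def test_published_design(self):
        # 14 degree difference, 14 degree SD, alpha 5%, power 80% -> 32 hips
        assert sample_size_two_group(14, 14, 0.05, 0.80) == 32

    def test_double_delta(self):
        assert sample_size_two_group(28, 14, 0.05, 0.80) == 8

    def test_large_delta_floor(self):
        assert sample_size_two_group(1e9, 14, 0.05, 0.80) == 2

    @pytest.mark.parametrize("bad", [dict(alpha=0), dict(power=1.0), dict(delta=-1)])
    def test_invalid_inputs_rejected(self, bad):
        kwargs = dict(delta=14.0, sd=14.0, alpha=0.05, power=0.8)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            sample_size_two_group(**kwargs)
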