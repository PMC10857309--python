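"""Window means, modulation-index algebra, slopes, t-tests, quadrant counts."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from cogvergence import (
    ModulationCurve,
    WindowDefinition,
    modulation_index,
    response_slope,
    sign_quadrant_counts,
    subject_modulation_index,
    two_tailed_t,
    window_mean,
)
from cogvergence.errors import DataError, WindowError


def _curve(v, t=None, cond="target"):
    v = np.asarray(v, float)
    t = np.arange(len(v)) * 100.0 if t is None else np.asarray(t, float)
    return ModulationCurve(t, v, 0.0, 1.0, cond)


class TestWindowMean:
    def test_constant_curve(self):
        assert window_mean(_curve(np.full(20, 0.7)), (0.0, 1000.0)) == pytest.approx(0.7)

    def test_hand_arithmetic(self):
        t = np.arange(0, 1000, 100.0)
        c = _curve(t / 1000.0, t)
        assert window_mean(c, (0.0, 200.0)) == pytest.approx(0.1)

    def test_single_grid_point_peak_window_at_30hz(self):
        t = np.arange(66) * (1000.0 / 30.0) - 200.0
        c = _curve(np.sin(t), t)
        # 400-433 ms holds exactly the t=400 grid point at 30 Hz
        idx = np.argmin(np.abs(t - 400.0))
        assert window_mean(c, (400.0, 433.0)) == pytest.approx(c.v[idx], abs=1e-12)

    def test_empty_window_raises(self):
        with pytest.raises(WindowError, match="500"):
            window_mean(_curve([1.0, 2.0], [0.0, 100.0]), (400.0, 500.0))

    def test_union_of_adjacent_windows_is_weighted_mean(self, rng):
        t = np.arange(30) * 50.0
        c = _curve(rng.normal(size=30), t)
        w1, w2 = (0.0, 500.0), (550.0, 1450.0)
        n1 = ((t >= w1[0]) & (t <= w1[1])).sum()
        n2 = ((t >= w2[0]) & (t <= w2[1])).sum()
        combined = window_mean(c, (0.0, 1450.0))
        weighted = (n1 * window_mean(c, w1) + n2 * window_mean(c, w2)) / (n1 + n2)
        assert combined == pytest.approx(weighted, abs=1e-12)


class TestModulationIndex:
    def test_equal_responses_give_zero(self):
        assert modulation_index(0.42, 0.42) == 0.0

    def test_paper_style_arithmetic(self):
        # peak means 0.036 (target) and -0.013 (distractor)
        assert modulation_index(0.036, -0.013) == pytest.approx(0.049 / 0.023, abs=1e-4)

    def test_absent_distractor_response_gives_one(self):
        assert modulation_index(0.5, 0.0) == 1.0

    @given(st.floats(-10, 10), st.floats(-10, 10))
    def test_antisymmetry_under_swap(self, T, D):
        a, b = modulation_index(T, D), modulation_index(D, T)
        if math.isnan(a):
            assert math.isnan(b)
        else:
            assert a == pytest.approx(-b, abs=1e-12)

    @given(st.floats(-5, 5), st.floats(-5, 5), st.floats(0.01, 50))
    def test_scale_invariance(self, T, D, a):
        base = modulation_index(T, D)
        scaled = modulation_index(a * T, a * D)
        if math.isnan(base):
            assert math.isnan(scaled) or abs(a * (T + D)) >= 1e-12
        else:
            assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)

    def test_degenerate_denominator_is_nan(self):
        assert math.isnan(modulation_index(1e-13, -1e-13))

    def test_unbounded_near_zero_denominator(self):
        assert abs(modulation_index(1.0, -0.999)) > 100


class TestSubjectSummary:
    def _trial(self, v_const, cond):
        t = np.arange(66) * (1000.0 / 30.0) - 200.0
        return ModulationCurve(t, np.full(66, v_const), 0.0, 1.0, cond)

    def test_identical_conditions_give_zero_mi(self):
        targets = [self._trial(0.3, "target")] * 3
        distractors = [self._trial(0.3, "distractor")] * 3
        s = subject_modulation_index(targets, distractors)
        assert s.mi == 0.0

    def test_flat_distractor_gives_unit_mi(self):
        s = subject_modulation_index(
            [self._trial(0.5, "target")] * 2, [self._trial(0.0, "distractor")] * 2)
        assert (s.T, s.D, s.mi) == (0.5, 0.0, 1.0)

    def test_matches_brute_force_on_random_instances(self, rng):
        windows = WindowDefinition()
        t = np.arange(66) * (1000.0 / 30.0) - 200.0
        for _ in range(25):
            targets = [ModulationCurve(t, rng.normal(size=66), 0, 1, "target")
                       for _ in range(rng.integers(1, 6))]
            distractors = [ModulationCurve(t, rng.normal(size=66), 0, 1, "distractor")
                           for _ in range(rng.integers(1, 6))]
            s = subject_modulation_index(targets, distractors, windows)
            lo, hi = windows.mi_window
            mask = (t >= lo - 1e-6) & (t <= hi + 1e-6)
            T = np.mean([c.v[mask].mean() for c in targets])
            D = np.mean([c.v[mask].mean() for c in distractors])
            assert s.T == pytest.approx(T, abs=1e-12)
            assert s.D == pytest.approx(D, abs=1e-12)
            assert s.mi == pytest.approx((T - D) / (T + D), abs=1e-9)

    def test_missing_condition_reported_not_raised(self):
        s = subject_modulation_index([self._trial(0.5, "target")], [])
        assert math.isnan(s.mi)
        assert "distractor" in s.reason


class TestSlope:
    def test_exact_linear_recovery(self):
        t = np.arange(60) * (1000.0 / 30.0)
        c = _curve(2.0 + 0.001 * t, t)
        assert response_slope(c, (0.0, 2000.0)) == pytest.approx(0.001, abs=1e-12)

    def test_constant_curve_zero_slope(self):
        assert response_slope(_curve(np.full(10, 3.3)), (0.0, 900.0)) == pytest.approx(0.0, abs=1e-15)

    def test_noisy_line_within_sampling_error(self, rng):
        t = np.arange(60) * (1000.0 / 30.0)
        slope_true, sd = 3e-5, 1e-3
        v = slope_true * t + rng.normal(0, sd, 60)
        est = response_slope(_curve(v, t), (0.0, 2000.0))
        se = sd / np.sqrt(np.sum((t - t.mean()) ** 2))
        assert abs(est - slope_true) < 3 * se

    def test_too_few_points_raises(self):
        with pytest.raises(WindowError):
            response_slope(_curve([1.0, 2.0], [0.0, 100.0]), (0.0, 50.0))


class TestTTest:
    def test_identical_samples_give_null_result(self):
        t, p = two_tailed_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)
        t, p = two_tailed_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)
        assert (t, p) == (0.0, 1.0)

    def test_separated_samples_give_tiny_p(self, rng):
        a = rng.normal(0.0, 1e-9, 4)
        b = 1.0 + rng.normal(0.0, 1e-9, 5)
        t, p = two_tailed_t(a, b)
        assert abs(t) > 1e6 and p < 1e-6

    def test_matches_textbook_closed_form_on_two_point_samples(self):
        # pooled Student t for n1=n2=2 has a short closed form
        a, b = np.array([0.0, 2.0]), np.array([5.0, 9.0])
        sp2 = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2
        expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (0.5 + 0.5))
        t, p = two_tailed_t(a, b, equal_var=True)
        assert t == pytest.approx(expected, abs=1e-10)
        assert p == pytest.approx(2 * stats.t.sf(abs(expected), 2), abs=1e-10)

    def test_welch_is_the_unpaired_default(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 3, 15)
        t, p = two_tailed_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-12)

    def test_undersized_samples_rejected(self):
        with pytest.raises(DataError):
            two_tailed_t([1.0], [1.0, 2.0])
        with pytest.raises(DataError):
            two_tailed_t([1.0, 2.0], [1.0, 2.0, 3.0], paired=True)


class TestQuadrantCounts:
    def test_all_positive(self):
        q = sign_quadrant_counts([(0.5, 1.2)] * 7)
        assert q.both_positive == 7 and q.n == 7
        assert q.fraction_positive() == (1.0, 1.0)

    def test_each_quadrant_once(self):
        q = sign_quadrant_counts([(1, 1), (1, -1), (-1, 1), (-1, -1)])
        assert (q.both_positive, q.first_only, q.second_only, q.neither) == (1, 1, 1, 1)
        assert q.fraction_positive() == (0.5, 0.5)

    def test_zero_counts_as_non_positive(self):
        q = sign_quadrant_counts([(0.0, 1.0), (0.0, 0.0)])
        assert q.second_only == 1 and q.neither == 1

    def test_missing_pairs_tallied_separately(self):
        q = sign_quadrant_counts([(math.nan, 1.0), (1.0, 1.0)])
        assert q.n_missing == 1 and q.both_positive == 1 and q.n == 1

    def test_matches_brute_force_tally(self, rng):
        pairs = [tuple(rng.normal(size=2)) for _ in range(12)]
        q = sign_quadrant_counts(pairs)
        brute = sum(1 for a, b in pairs if a > 0 and b > 0)
        assert q.both_positive == brute
        assert q.n == 12
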