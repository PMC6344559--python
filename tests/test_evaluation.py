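"""Diagnostic statistics: Wilson CC intervals, test characteristics,
ROC/AUC, Yates chi-square, Mann-Whitney U, descriptives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from sepsitree.evaluation import (
    ConfusionTable,
    EvaluationError,
    chi_square_yates,
    confusion_from_predictions,
    format_p,
    lr_from_rates,
    mann_whitney_u,
    median_iqr,
    roc_auc_with_ci,
    roc_points,
    test_characteristics as compute_characteristics,
    wilson_cc_interval,
)


class TestConfusion:
    def test_hand_count(self):
        t = confusion_from_predictions([1, 1, 0], [1, 0, 0])
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 1, 0, 1)

    def test_all_correct(self):
        t = confusion_from_predictions([1, 0, 1], [1, 0, 1])
        assert t.fp == t.fn == 0

    def test_inverted(self):
        t = confusion_from_predictions([0, 1], [1, 0])
        assert t.tp == t.tn == 0

    def test_length_mismatch(self):
        with pytest.raises(EvaluationError):
            confusion_from_predictions([1], [1, 0])


class TestWilsonCC:
    def test_all_successes_small_n(self):
        ci = wilson_cc_interval(21, 21)
        assert ci.estimate == 1.0
        assert ci.upper == 1.0
        assert ci.lower == pytest.approx(0.8076, abs=5e-4)

    def test_zero_successes_clipped(self):
        ci = wilson_cc_interval(0, 10)
        assert ci.lower == 0.0
        assert ci.estimate == 0.0

    def test_symmetry_at_half(self):
        ci = wilson_cc_interval(50, 100)
        assert ci.lower + ci.upper == pytest.approx(1.0, abs=1e-12)

    @given(n=st.integers(1, 500), frac=st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_contains_estimate(self, n, frac):
        k = round(frac * n)
        ci = wilson_cc_interval(k, n)
        assert ci.lower <= ci.estimate <= ci.upper

    @pytest.mark.parametrize("k_over_n", [0.1, 0.5, 0.9])
    def test_width_shrinks_with_n(self, k_over_n):
        widths = []
        for n in (20, 80, 320, 1280):
            ci = wilson_cc_interval(round(k_over_n * n), n)
            widths.append(ci.upper - ci.lower)
        assert widths == sorted(widths, reverse=True)


class TestTestCharacteristics:
    def test_mortality_style_table(self):
        """21 events all captured, 119 false positives, 260 true negatives:
        perfect sensitivity and NPV, PPV 15%, LR+ ~3.2, LR- undefined."""
        tc = compute_characteristics(ConfusionTable(tp=21, fp=119, fn=0, tn=260))
        assert tc.sensitivity.estimate == 1.0
        assert tc.npv.estimate == 1.0
        assert tc.ppv.estimate == pytest.approx(0.15, abs=0.005)
        assert tc.specificity.estimate == pytest.approx(0.686, abs=0.001)
        assert tc.lr_positive.estimate == pytest.approx(3.18, abs=0.01)
        assert not tc.lr_negative.defined
        assert tc.sensitivity.lower == pytest.approx(0.81, abs=0.005)

    def test_lr_from_rounded_rates(self):
        lr_pos, lr_neg = lr_from_rates(0.86, 0.67)
        assert round(lr_pos, 1) == 2.6
        assert round(lr_neg, 1) == 0.2
        lr_pos, _ = lr_from_rates(1.0, 0.69)
        assert round(lr_pos, 1) == 3.2

    def test_no_positive_predictions_ppv_undefined(self):
        tc = compute_characteristics(ConfusionTable(tp=0, fp=0, fn=5, tn=5))
        assert tc.ppv is None
        assert not tc.lr_positive.defined  # specificity is exactly 1 here

    def test_fn_zero_gives_exact_ones(self):
        tc = compute_characteristics(ConfusionTable(tp=7, fp=3, fn=0, tn=30))
        assert tc.sensitivity.estimate == 1.0
        assert tc.npv.estimate == 1.0

    def test_lr_identity(self):
        tc = compute_characteristics(ConfusionTable(tp=51, fp=112, fn=9, tn=228))
        sens, spec = tc.sensitivity.estimate, tc.specificity.estimate
        assert tc.lr_positive.estimate == pytest.approx(sens / (1 - spec), abs=1e-12)
        assert tc.lr_negative.estimate == pytest.approx((1 - sens) / spec, abs=1e-12)


class TestRoc:
    def test_perfect_separation(self):
        r = roc_auc_with_ci([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_complete_ties(self):
        r = roc_auc_with_ci([0.3, 0.3, 0.3, 0.3], [1, 0, 1, 0])
        assert r.auc == pytest.approx(0.5)

    def test_hand_example(self):
        r = roc_auc_with_ci([0.52, 0.22, 0.038, 0.22], [1, 0, 0, 1])
        assert r.auc == pytest.approx(0.875)

    def test_single_class_error(self):
        with pytest.raises(EvaluationError):
            roc_auc_with_ci([0.1, 0.2], [1, 1])

    def test_points_monotone(self):
        rng = np.random.default_rng(0)
        pts = roc_points(rng.random(50), rng.random(50) < 0.4)
        arr = np.asarray(pts)
        assert (np.diff(arr[:, 0]) >= 0).all()
        assert (np.diff(arr[:, 1]) >= 0).all()

    def test_equals_rank_statistic(self):
        """Trapezoidal AUC == tie-corrected U / (n1*n0), fuzzed."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(4, 60))
            risks = rng.choice([0.1, 0.2, 0.2, 0.5, 0.9], size=n)
            y = rng.random(n) < 0.4
            if y.all() or not y.any():
                continue
            u = sps.mannwhitneyu(risks[y], risks[~y], alternative="two-sided").statistic
            auc_rank = u / (y.sum() * (~y).sum())
            assert roc_auc_with_ci(risks, y).auc == pytest.approx(auc_rank, abs=1e-10)

    def test_against_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        risks = rng.random(300)
        y = rng.random(300) < 0.3
        assert roc_auc_with_ci(risks, y).auc == pytest.approx(
            roc_auc_score(y, risks), abs=1e-12
        )


class TestChiSquare:
    def test_no_association_is_zero(self):
        assert chi_square_yates(10, 10, 10, 10).statistic == 0.0

    def test_matches_scipy_contingency(self):
        res = chi_square_yates(30, 70, 10, 90)
        ref = sps.chi2_contingency([[30, 70], [10, 90]], correction=True)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    @given(
        a=st.integers(1, 200), b=st.integers(1, 200),
        c=st.integers(1, 200), d=st.integers(1, 200),
    )
    @settings(max_examples=100, deadline=None)
    def test_transpose_and_relabel_invariance(self, a, b, c, d):
        s = chi_square_yates(a, b, c, d).statistic
        assert chi_square_yates(a, c, b, d).statistic == pytest.approx(s)
        assert chi_square_yates(d, c, b, a).statistic == pytest.approx(s)

    def test_zero_marginal_error(self):
        with pytest.raises(EvaluationError):
            chi_square_yates(0, 0, 5, 5)


class TestMannWhitney:
    def test_exact_no_overlap(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.exact
        assert res.p_value == pytest.approx(0.1)

    def test_identical_samples_central_u(self):
        res = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.u == pytest.approx(8.0)  # n^2 / 2

    def test_shifted_maximal(self):
        res = mann_whitney_u([101, 102, 103], [1, 2, 3])
        assert res.u == 9.0

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 40).round(1)
        y = rng.normal(0.5, 1, 35).round(1)
        res = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
        assert res.u == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_empty_error(self):
        with pytest.raises(EvaluationError):
            mann_whitney_u([], [1.0])


class TestDescriptives:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, 2, 3, 4, 5], (3, 2, 4)),
            ([7], (7, 7, 7)),
            ([2, 2, 2, 2], (2, 2, 2)),
        ],
    )
    def test_median_iqr(self, values, expected):
        assert median_iqr(values) == pytest.approx(expected)

    def test_empty_error(self):
        with pytest.raises(EvaluationError):
            median_iqr([])

    def test_p_format(self):
        assert format_p(0.0004) == "<0.001"
        assert format_p(0.049) == "0.049"
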