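"""Metric arithmetic, probability summaries, rank-test contrasts.

The reference confusion matrix used throughout (a published validation of
this modelling design: 308 invasive and 115 native hold-out points) is
TP=241, FN=67, FP=24, TN=91 in the invasive-positive orientation.
"""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nichecontrast as nc
from nichecontrast.evaluation import round_half_up
from nichecontrast.geodata_io import INVASIVE, NATIVE

from conftest import make_labelled_table

REFERENCE_CM = nc.ConfusionMatrix(TP=241, FN=67, FP=24, TN=91)


class TestConfusion:
    def test_all_invasive_correct(self):
        cm = nc.confusion([INVASIVE] * 5, [INVASIVE] * 5)
        assert (cm.TP, cm.FN, cm.FP, cm.TN) == (5, 0, 0, 0)

    def test_counts_from_label_pairs(self):
        obs = [INVASIVE, INVASIVE, NATIVE, NATIVE, INVASIVE]
        pred = [INVASIVE, NATIVE, NATIVE, INVASIVE, INVASIVE]
        cm = nc.confusion(obs, pred)
        assert (cm.TP, cm.FN, cm.FP, cm.TN) == (2, 1, 1, 1)

    def test_orientation_swap_exchanges_tp_tn_and_fp_fn(self):
        sw = REFERENCE_CM.swapped()
        assert (sw.TP, sw.FN, sw.FP, sw.TN) == (91, 24, 67, 241)
        assert sw.swapped() == REFERENCE_CM

    def test_length_mismatch_and_foreign_labels_rejected(self):
        with pytest.raises(ValueError, match="length"):
            nc.confusion([INVASIVE], [INVASIVE, NATIVE])
        with pytest.raises(ValueError, match="foreign"):
            nc.confusion([INVASIVE], ["weird"])


class TestClassMetrics:
    def test_reference_invasive_orientation(self):
        m = nc.class_metrics(REFERENCE_CM)
        assert (round_half_up(m.precision), round_half_up(m.recall),
                round_half_up(m.f1)) == (0.91, 0.78, 0.84)
        assert m.n == 308

    def test_reference_native_orientation(self):
        m = nc.class_metrics(REFERENCE_CM.swapped())
        assert (round_half_up(m.precision), round_half_up(m.recall),
                round_half_up(m.f1)) == (0.58, 0.79, 0.67)
        assert m.n == 115

    def test_harmonic_mean_identity(self):
        cm = nc.ConfusionMatrix(TP=30, FN=10, FP=10, TN=50)
        m = nc.class_metrics(cm)
        assert m.precision == m.recall == 0.75
        assert m.f1 == pytest.approx(0.75)

    def test_zero_denominators_are_undefined_not_zero(self):
        m = nc.class_metrics(nc.ConfusionMatrix(TP=0, FN=0, FP=0, TN=10))
        assert math.isnan(m.precision) and math.isnan(m.recall)
        assert math.isnan(m.f1)
        assert not m.defined

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500),
           st.integers(0, 500))
    def test_matches_exact_fraction_arithmetic(self, tp, fn, fp, tn):
        """Brute-force oracle: precision/recall/f1 as exact fractions."""
        m = nc.class_metrics(nc.ConfusionMatrix(TP=tp, FN=fn, FP=fp, TN=tn))
        if tp + fp:
            assert m.precision == pytest.approx(Fraction(tp, tp + fp))
        else:
            assert math.isnan(m.precision)
        if tp + fn:
            assert m.recall == pytest.approx(Fraction(tp, tp + fn))
        else:
            assert math.isnan(m.recall)
        if (tp + fp) and (tp + fn):
            if tp == 0:  # P = R = 0: harmonic mean is 0/0, undefined
                assert math.isnan(m.f1)
            else:
                expected = Fraction(2 * tp, 2 * tp + fp + fn)
                assert m.f1 == pytest.approx(expected)
                assert min(m.precision, m.recall) - 1e-12 <= m.f1
                assert m.f1 <= max(m.precision, m.recall) + 1e-12

    def test_recount_from_random_label_pairs(self):
        """Metrics from confusion() agree with sklearn recounts."""
        from sklearn.metrics import precision_recall_fscore_support
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(2, 60))
            obs = np.where(rng.random(n) < 0.5, INVASIVE, NATIVE)
            pred = np.where(rng.random(n) < 0.5, INVASIVE, NATIVE)
            cm = nc.confusion(obs, pred)
            m = nc.class_metrics(cm)
            p, r, f, _ = precision_recall_fscore_support(
                obs == INVASIVE, pred == INVASIVE, average="binary",
                zero_division=np.nan)
            for ours, ref in ((m.precision, p), (m.recall, r), (m.f1, f)):
                assert (math.isnan(ours) and math.isnan(ref)) or \
                    ours == pytest.approx(ref)


class TestWeightedMetrics:
    def test_reference_weighted_row(self):
        m_inv = nc.class_metrics(REFERENCE_CM)
        m_nat = nc.class_metrics(REFERENCE_CM.swapped())
        w = nc.weighted_metrics(m_inv, m_nat)
        assert (round_half_up(w.precision), round_half_up(w.recall),
                round_half_up(w.f1)) == (0.82, 0.78, 0.79)

    def test_weighted_f1_from_stated_pair(self):
        """f1 pair (0.8411, 0.6666) at n = (308, 115) -> 0.79 at 2 d.p."""
        m_inv = nc.ClassMetrics(precision=0.9094, recall=0.7825, f1=0.8411,
                                n=308)
        m_nat = nc.ClassMetrics(precision=0.5759, recall=0.7913, f1=0.6666,
                                n=115)
        w = nc.weighted_metrics(m_inv, m_nat)
        assert round_half_up(w.f1) == 0.79
        assert round_half_up(w.precision) == 0.82

    def test_equal_class_values_pass_through(self):
        m = nc.ClassMetrics(precision=0.6, recall=0.6, f1=0.6, n=10)
        m2 = nc.ClassMetrics(precision=0.6, recall=0.6, f1=0.6, n=990)
        w = nc.weighted_metrics(m, m2)
        assert w.precision == w.recall == w.f1 == pytest.approx(0.6)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1), st.integers(1, 1000),
           st.integers(1, 1000))
    def test_weighted_mean_lies_between_class_values(self, a, b, na, nb):
        m1 = nc.ClassMetrics(precision=a, recall=a, f1=a, n=na)
        m2 = nc.ClassMetrics(precision=b, recall=b, f1=b, n=nb)
        w = nc.weighted_metrics(m1, m2)
        assert min(a, b) - 1e-12 <= w.f1 <= max(a, b) + 1e-12
        expected = (a * na + b * nb) / (na + nb)
        assert w.f1 == pytest.approx(expected)

    def test_zero_total_observations_rejected(self):
        m = nc.ClassMetrics(math.nan, math.nan, math.nan, 0)
        with pytest.raises(ValueError, match="zero total"):
            nc.weighted_metrics(m, m)


class TestProbabilitySummary:
    def test_median_of_three(self):
        s = nc.summarize_probabilities([0.1, 0.5, 0.9])
        assert s.median == 0.5

    def test_constant_sample_collapses_quartiles(self):
        s = nc.summarize_probabilities([0.3] * 7)
        assert s.q1 == s.median == s.q3 == 0.3

    def test_histogram_counts_sum_to_n_on_ten_bins(self):
        rng = np.random.default_rng(1)
        s = nc.summarize_probabilities(rng.random(137))
        assert len(s.counts) == 10
        assert sum(s.counts) == s.n == 137
        assert s.q1 <= s.median <= s.q3

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_quartiles_match_sort_based_oracle(self, probs):
        """Linear-interpolation quantiles against a direct order-statistic
        computation."""
        s = nc.summarize_probabilities(probs)
        v = np.sort(np.asarray(probs))

        def quantile(q):
            h = (len(v) - 1) * q
            lo = int(math.floor(h))
            hi = min(lo + 1, len(v) - 1)
            return v[lo] + (h - lo) * (v[hi] - v[lo])

        assert s.q1 == pytest.approx(quantile(0.25), abs=1e-12)
        assert s.median == pytest.approx(quantile(0.5), abs=1e-12)
        assert s.q3 == pytest.approx(quantile(0.75), abs=1e-12)

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nc.summarize_probabilities([])
        with pytest.raises(ValueError):
            nc.summarize_probabilities([0.5, 1.2])


def exact_mannwhitney_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by dynamic programming over the
    null distribution of U (no ties), independent of scipy."""
    from functools import lru_cache

    n, m = len(x), len(y)

    @lru_cache(maxsize=None)
    def f(nn, mm, uu):
        if uu < 0:
            return 0
        if nn == 0:
            return 1 if uu == 0 else 0
        if mm == 0:
            return 1 if uu == 0 else 0
        return f(nn - 1, mm, uu - mm) + f(nn, mm - 1, uu)

    u_obs = sum(1 for xi in x for yi in y if xi > yi) + \
        0.5 * sum(1 for xi in x for yi in y if xi == yi)
    total = math.comb(n + m, n)
    cdf_ge = sum(f(n, m, u) for u in range(int(math.ceil(u_obs)), n * m + 1))
    cdf_le = sum(f(n, m, u) for u in range(0, int(math.floor(u_obs)) + 1))
    return min(1.0, 2 * min(cdf_ge, cdf_le) / total)


class TestClassContrast:
    def _table(self, inv_values, nat_values):
        return make_labelled_table(
            np.asarray(inv_values, dtype=float)[:, None],
            np.asarray(nat_values, dtype=float)[:, None], ["V"])

    def test_identical_samples_give_p_one(self):
        table = self._table([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        res = nc.class_contrast(table, "V")
        assert res["p_value"] == 1.0

    def test_fully_separated_samples_give_tiny_p(self):
        table = self._table(np.arange(1, 21), np.arange(101, 121))
        res = nc.class_contrast(table, "V")
        assert res["p_value"] < 1e-6
        assert res["p_value"] == pytest.approx(
            exact_mannwhitney_p(np.arange(1, 21), np.arange(101, 121)),
            rel=1e-6)

    def test_small_samples_match_exact_distribution_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(0, 1, size=int(rng.integers(3, 12)))
            y = rng.normal(0.5, 1, size=int(rng.integers(3, 12)))
            table = self._table(x, y)
            res = nc.class_contrast(table, "V")
            assert res["method"] == "exact"
            assert res["p_value"] == pytest.approx(
                exact_mannwhitney_p(x, y), rel=1e-9)

    def test_large_samples_use_tie_corrected_approximation(self):
        rng = np.random.default_rng(4)
        table = self._table(rng.normal(0, 1, 50), rng.normal(0, 1, 50))
        res = nc.class_contrast(table, "V")
        assert res["method"] == "asymptotic"
        assert 0 <= res["p_value"] <= 1

    def test_empty_class_rejected(self):
        table = self._table([1.0], [2.0])
        table = table.subset((table.data["label"] == INVASIVE).to_numpy())
        df = table.data  # single-class table cannot be built: construct raw
        df = pd.concat([df], ignore_index=True)
        t = nc.FeatureTable(df, ["V"])
        with pytest.raises(ValueError, match="zero values"):
            nc.class_contrast(t, "V")

    def test_unknown_variable_rejected(self):
        table = self._table([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError, match="not in table"):
            nc.class_contrast(table, "Q")


class TestRounding:
    def test_half_up_at_the_boundary(self):
        assert round_half_up(0.785) == 0.79
        assert round_half_up(0.784999) == 0.78
        assert round_half_up(0.125, 2) == 0.13
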