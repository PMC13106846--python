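"""Welch comparison, oriented AUC, ranking and diagnostic metrics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import auc_oracle, welch_oracle
from ecgcomplexity._exceptions import (
    InsufficientDataError,
    ParameterError,
    UndefinedMetricError,
)
from ecgcomplexity.correction import SubjectScore
from ecgcomplexity.evaluation import (
    classify_threshold,
    compare_groups,
    confusion_from_rates,
    diagnostic_metrics,
    rank_algorithms,
    roc_auc,
    welch_t_test,
)


class TestWelch:
    def test_identical_groups(self):
        t, _, p = welch_t_test([1.0, 2, 3], [1.0, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_closed_form(self):
        a, b = [1.0, 2, 3, 4], [2.0, 4, 6, 8]
        t, df, p = welch_t_test(a, b)
        t_ref, df_ref = welch_oracle(a, b)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert df == pytest.approx(df_ref, abs=1e-10)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_ref), df_ref), abs=1e-10)

    def test_swap_flips_sign_only(self):
        a, b = [1.0, 2, 3, 4], [2.0, 4, 6, 9]
        ta, _, pa = welch_t_test(a, b)
        tb, _, pb = welch_t_test(b, a)
        assert ta == pytest.approx(-tb)
        assert pa == pytest.approx(pb)

    def test_degenerate_data(self):
        with pytest.raises(UndefinedMetricError):
            welch_t_test([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(InsufficientDataError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_permutation_null_calibration(self):
        """Under label permutation the Welch test rejects at ~5%: the
        fraction of p < 0.05 over 1000 permutations is 5% +- 2%."""
        rng = np.random.default_rng(19)
        values = rng.normal(size=30)
        rejected = 0
        for _ in range(1000):
            perm = rng.permutation(30)
            _, _, p = welch_t_test(values[perm[:15]], values[perm[15:]])
            rejected += p < 0.05
        assert 0.03 <= rejected / 1000 <= 0.07


class TestRocAuc:
    def test_perfect_separation_cases_low(self):
        assert roc_auc([3.0, 4.0, 1.0, 2.0], ["control", "control", "case", "case"]) == 1.0

    def test_interleaved_example(self):
        assert roc_auc([1.0, 3.0, 2.0, 4.0], ["control", "control", "case", "case"]) == 0.25

    def test_all_ties(self):
        assert roc_auc([5.0] * 6, ["case"] * 3 + ["control"] * 3) == 0.5

    def test_one_class_empty(self):
        with pytest.raises(ParameterError):
            roc_auc([1.0, 2.0], ["case", "case"])

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = rng.choice(["case", "control"], size=n)
            if len(set(labels)) < 2:
                continue
            assert roc_auc(scores, labels) == pytest.approx(auc_oracle(scores, labels))

    def test_sign_flip_mirrors_auc(self):
        rng = np.random.default_rng(22)
        scores = rng.normal(size=30)
        labels = rng.choice(["case", "control"], size=30)
        assert roc_auc(-scores, labels) == pytest.approx(1.0 - roc_auc(scores, labels))


class TestCompareGroups:
    def _scores(self, case_values, control_values):
        out = [SubjectScore(f"c{i}", "case", v, 1) for i, v in enumerate(case_values)]
        out += [SubjectScore(f"k{i}", "control", v, 1) for i, v in enumerate(control_values)]
        return out

    def test_bundles_t_and_auc(self):
        comparison = compare_groups(self._scores([0.1, 0.2, 0.15], [0.4, 0.5, 0.45]),
                                    estimator="LZ76", mask=44, band=(60, 100))
        assert comparison.p < 0.05
        assert comparison.auc == 1.0
        assert comparison.mean_control > comparison.mean_case

    def test_single_subject_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_groups(self._scores([0.1], [0.4, 0.5]))


class TestRankAlgorithms:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["estimator", "mask", "p", "auc"])

    def test_lowest_p_first(self):
        ranked = rank_algorithms(self._frame([("LZ76", 1, 0.02, 0.7), ("LZ76", 2, 0.01, 0.6)]))
        assert ranked.iloc[0]["mask"] == 2

    def test_auc_breaks_p_ties(self):
        ranked = rank_algorithms(self._frame([("LZ76", 1, 0.01, 0.8), ("LZ76", 2, 0.01, 0.9)]))
        assert ranked.iloc[0]["mask"] == 2

    def test_full_tie_resolved_by_mask_code(self):
        ranked = rank_algorithms(self._frame([("LZ76", 9, 0.01, 0.9), ("LZ76", 3, 0.01, 0.9)]))
        assert ranked.iloc[0]["mask"] == 3


class TestDiagnosticMetrics:
    def test_worked_example_from_screening_study(self):
        """A 7-positive / 60-negative screening cohort with Se 85.7% and
        Sp 83.3% has the unique confusion matrix (6,1,50,10); predictive
        values and all Wald CIs follow to one decimal."""
        candidates = confusion_from_rates(85.7, 7, 83.3, 60)
        assert candidates == [(6, 1, 50, 10)]
        tp, fn, tn, fp = candidates[0]
        m = diagnostic_metrics(tp, fp, tn, fn)
        assert m.sensitivity == pytest.approx(85.7, abs=0.05)
        assert m.sensitivity_ci == pytest.approx((59.8, 100.0), abs=0.05)
        assert m.specificity == pytest.approx(83.3, abs=0.05)
        assert m.specificity_ci == pytest.approx((73.9, 92.8), abs=0.05)
        assert m.ppv == pytest.approx(37.5, abs=0.05)
        assert m.ppv_ci == pytest.approx((13.8, 61.2), abs=0.05)
        assert m.npv == pytest.approx(98.0, abs=0.05)
        assert m.npv_ci == pytest.approx((94.2, 100.0), abs=0.05)

    def test_perfect_classifier(self):
        m = diagnostic_metrics(1, 0, 1, 0)
        assert m.sensitivity == m.specificity == m.ppv == m.npv == 100.0
        assert m.cui_positive == pytest.approx(1.0)
        assert m.cui_negative == pytest.approx(1.0)

    def test_undefined_ppv_flagged(self):
        m = diagnostic_metrics(0, 0, 1, 1)
        assert m.ppv is None and m.ppv_ci is None and m.cui_positive is None
        assert m.npv is not None

    def test_cui_products(self):
        m = diagnostic_metrics(6, 10, 50, 1)
        assert m.cui_positive == pytest.approx((6 / 7) * (6 / 16))
        assert m.cui_negative == pytest.approx((50 / 60) * (50 / 51))

    def test_ci_clipped_to_unit_interval(self):
        m = diagnostic_metrics(5, 0, 5, 0)
        assert m.sensitivity_ci == (100.0, 100.0)

    def test_input_validation(self):
        with pytest.raises(ParameterError):
            diagnostic_metrics(-1, 0, 1, 1)
        with pytest.raises(ParameterError):
            diagnostic_metrics(0, 0, 0, 0)


class TestClassifyThreshold:
    def _scores(self):
        case = [SubjectScore(f"c{i}", "case", v, 1) for i, v in enumerate([-0.3, -0.2, -0.25])]
        ctrl = [SubjectScore(f"k{i}", "control", v, 1) for i, v in enumerate([0.1, 0.2, 0.15, 0.3])]
        return case + ctrl

    def test_threshold_below_everything(self):
        tp, fp, tn, fn = classify_threshold(self._scores(), -1.0)
        assert (tp, fp) == (0, 0) and tn == 4 and fn == 3

    def test_threshold_above_everything(self):
        tp, fp, tn, fn = classify_threshold(self._scores(), 1.0)
        assert (tn, fn) == (0, 0) and tp == 3 and fp == 4

    def test_youden_optimal_on_separable_scores(self):
        scores = self._scores()
        values = sorted(s.score for s in scores)
        best = None
        for threshold in [(a + b) / 2 for a, b in zip(values, values[1:])]:
            tp, fp, tn, fn = classify_threshold(scores, threshold)
            m = diagnostic_metrics(tp, fp, tn, fn)
            j = m.sensitivity + m.specificity
            if best is None or j > best[0]:
                best = (j, m)
        assert best[1].sensitivity == 100.0 and best[1].specificity == 100.0

    def test_nonfinite_threshold_rejected(self):
        with pytest.raises(ParameterError):
            classify_threshold(self._scores(), float("nan"))
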