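"""The 16-metric evaluation framework: confusion counts, OFO/NPV, curve
areas, the 3-point dichotomous rule, stratifiers and significance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from fvc.classifier import FILTERED, RETAINED
from fvc.features import FEATURE_NAMES, FeatureVector
from fvc.metrics import (
    METRIC_NAMES, ConfusionCounts, aggregate_reports, confusion,
    curve_metrics, full_report, npv, ofo, paired_onesided_ttest,
    significance_stars, stratify, three_point_curve_metrics,
    threshold_metrics,
)
from fvc.truthset import LabeledExample


def _counts(tp=0, fp=0, fn=0, tn=0):
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


class TestConfusion:
    def test_hand_counted_example(self):
        c = confusion([True, True, False, False],
                      [RETAINED, FILTERED, RETAINED, FILTERED])
        assert (c.TP, c.FN, c.FP, c.TN) == (1, 1, 1, 1)

    def test_perfect_filter_has_no_errors(self):
        c = confusion([True, False], [RETAINED, FILTERED])
        assert c.FP == 0 and c.FN == 0

    def test_empty_input_all_zero(self):
        c = confusion([], [])
        assert c.total == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([True], [])


class TestNpvOfo:
    def test_npv_simple(self):
        assert npv(_counts(tn=1)) == 1.0
        assert npv(_counts(tn=0, fn=5)) == 0.0
        assert math.isnan(npv(_counts(tp=3)))

    def test_npv_reported_snv_counts(self):
        # eliminated set of 5,869 false and 425 true variants
        assert round(npv(_counts(tn=5869, fn=425)), 2) == 0.93

    def test_ofo_single_false_variant_eliminated_is_zero(self):
        assert ofo(_counts(fn=0, tn=1)) == 0.0

    def test_ofo_one_when_eliminated_classes_balance(self):
        assert ofo(_counts(fn=7, tn=7)) == 1.0

    def test_ofo_reported_indel_counts(self):
        assert round(ofo(_counts(fn=86, tn=543)), 2) == 0.16

    def test_ofo_edge_cases(self):
        assert ofo(_counts(fn=3, tn=0)) == math.inf
        assert math.isnan(ofo(_counts(tp=10)))


class TestThresholdMetrics:
    def test_perfect_filter(self):
        m = threshold_metrics(_counts(tp=50, tn=5))
        assert m["MCC"] == 1.0 and m["BACC"] == 1.0
        assert m["F1_major"] == 1.0 and m["F1_minor"] == 1.0

    def test_uniform_table_hand_arithmetic(self):
        m = threshold_metrics(_counts(1, 1, 1, 1))
        assert m["MCC"] == 0.0
        assert m["ACC"] == 0.5 and m["BACC"] == 0.5
        assert m["Precision"] == 0.5 and m["NPV"] == 0.5 and m["OFO"] == 1.0

    def test_random_verdicts_mcc_near_zero(self):
        rng = np.random.default_rng(0)
        labels = rng.random(20000) < 0.5
        verdicts = [RETAINED if x else FILTERED for x in rng.random(20000) < 0.5]
        m = threshold_metrics(confusion(labels, verdicts))
        assert abs(m["MCC"]) < 0.02

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 500), st.integers(0, 500),
           st.integers(0, 500), st.integers(0, 500))
    def test_identities_on_random_tables(self, tp, fp, fn, tn):
        c = _counts(tp, fp, fn, tn)
        m = threshold_metrics(c)
        if tn + fn > 0:
            for_ = fn / (tn + fn)
            assert m["NPV"] + for_ == pytest.approx(1.0)
            if tn > 0:
                assert m["OFO"] == pytest.approx(for_ / m["NPV"])
                assert m["OFO"] == pytest.approx(fn / tn)
        if not math.isnan(m["MCC"]):
            assert -1.0 <= m["MCC"] <= 1.0 + 1e-12
        if not math.isnan(m["BACC"]):
            assert m["BACC"] == pytest.approx(
                (m["Sensitivity"] + m["Specificity"]) / 2)
        if c.total:
            assert m["ACC"] == pytest.approx((tp + tn) / c.total)


def _concordance_auc(labels, scores):
    """Exhaustive pairwise-comparison oracle for the ROC area."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))


class TestCurveMetrics:
    def test_perfect_scores_give_auc_one(self):
        labels = [True, True, False, False]
        scores = [1.0, 1.0, 0.0, 0.0]
        m = curve_metrics(labels, scores)
        assert m["AUC"] == 1.0
        assert m["AUPRG"] == pytest.approx(1.0)

    def test_auc_equals_pairwise_concordance_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(10, 200)
            labels = rng.random(n) < rng.uniform(0.2, 0.8)
            if labels.all() or not labels.any():
                continue
            scores = np.round(rng.random(n), 2)  # ties included
            m = curve_metrics(labels, scores)
            assert m["AUC"] == pytest.approx(_concordance_auc(labels, scores))

    def test_uninformative_scores_auc_half(self):
        rng = np.random.default_rng(1)
        labels = rng.random(20000) < 0.5
        scores = rng.random(20000)
        assert curve_metrics(labels, scores)["AUC"] == pytest.approx(0.5, abs=0.02)

    def test_single_class_is_missing(self):
        m = curve_metrics([True, True], [0.5, 0.9])
        assert all(math.isnan(v) for v in m.values())


class TestThreePoint:
    def test_perfect_operating_point(self):
        assert three_point_curve_metrics(_counts(tp=10, tn=10), "AUC") == 1.0

    def test_chance_diagonal_point(self):
        # x2 == y2 lies on the diagonal: area 0.5
        c = _counts(tp=6, fn=4, fp=6, tn=4)  # TPR = FPR = 0.6
        assert three_point_curve_metrics(c, "AUC") == pytest.approx(0.5)

    def test_trapezoid_closed_form(self):
        # operating point (FPR, TPR) = (0.2, 0.8)
        c = _counts(tp=80, fn=20, fp=20, tn=80)
        expected = (0.2 * 0.8) / 2 + (1 - 0.2) * (0.8 + 1) / 2
        assert three_point_curve_metrics(c, "AUC") == pytest.approx(expected)
        assert expected == pytest.approx(0.8)

    def test_two_independent_trapezoid_formulas_agree(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(1, 100, size=4)
            c = _counts(int(tp), int(fp), int(fn), int(tn))
            x2 = fp / (fp + tn)
            y2 = tp / (tp + fn)
            closed_form = (x2 * y2 + (1 - x2) * (y2 + 1)) / 2
            assert three_point_curve_metrics(c, "AUC") == pytest.approx(closed_form)

    def test_pr_variants_bounded(self):
        c = _counts(tp=80, fn=20, fp=20, tn=80)
        for which in ("AUPRC", "AUPRG"):
            v = three_point_curve_metrics(c, which)
            assert 0.0 <= v <= 1.0


class TestFullReportAndAggregation:
    def test_report_names_all_sixteen_metrics(self):
        rep = full_report([True, False], [RETAINED, FILTERED], scores=[0.9, 0.1])
        assert list(rep) == METRIC_NAMES
        assert len([n for n in METRIC_NAMES if n not in ("TP", "FP", "FN", "TN")]) == 13

    def test_mean_and_pooled_aggregation_disagree_for_ratios(self):
        r1 = full_report([True] * 5 + [False] * 5,
                         [RETAINED] * 5 + [FILTERED] * 5)
        r2 = full_report([True] * 9 + [False],
                         [RETAINED] * 8 + [FILTERED, RETAINED])
        agg = aggregate_reports([r1, r2])
        assert agg["mean"]["TN"] == r1["TN"] + r2["TN"]
        assert set(agg) == {"mean", "pooled"}

    def test_pooling_strata_reproduces_pooled_confusion(self):
        rng = np.random.default_rng(5)
        labels = rng.random(300) < 0.7
        verdicts = [RETAINED if x else FILTERED for x in rng.random(300) < 0.6]
        whole = confusion(labels, verdicts)
        half = 150
        parts = [confusion(labels[:half], verdicts[:half]),
                 confusion(labels[half:], verdicts[half:])]
        assert whole.TP == sum(p.TP for p in parts)
        assert whole.TN == sum(p.TN for p in parts)


def _example(vaf, chrom="1", pos=1):
    key = (chrom, pos, "C", "T", "S1")
    vals = dict.fromkeys(FEATURE_NAMES, 1.0)
    vals["VAF"] = vaf
    return LabeledExample(key, FeatureVector(key, vals), True)


class TestStratify:
    def test_vaf_boundary_assigned_high(self):
        strata = stratify([_example(0.20, pos=1), _example(0.19, pos=2)], "vaf")
        assert [e.features.values["VAF"] for e in strata["high_vaf"]] == [0.20]
        assert [e.features.values["VAF"] for e in strata["low_vaf"]] == [0.19]

    def test_difficulty_easy_iff_all_baselines_correct(self):
        exs = [_example(0.5, pos=p) for p in (1, 2, 3)]
        labels = [True, True, False]
        b1 = [RETAINED, RETAINED, FILTERED]   # all correct
        b2 = [RETAINED, FILTERED, FILTERED]   # wrong on example 2
        strata = stratify(exs, "difficulty",
                          {"labels": labels, "baseline_verdicts": [b1, b2]})
        assert [e.key[1] for e in strata["easy"]] == [1, 3]
        assert [e.key[1] for e in strata["hard"]] == [2]

    def test_region_partition(self):
        exs = [_example(0.5, pos=50), _example(0.5, pos=500)]
        strata = stratify(exs, "region", {"1": [(1, 100)]})
        assert len(strata["coding"]) == 1 and len(strata["noncoding"]) == 1

    def test_strata_sizes_sum_to_input(self):
        exs = [_example(v, pos=i + 1) for i, v in
               enumerate(np.linspace(0.01, 0.99, 17))]
        strata = stratify(exs, "vaf")
        assert sum(map(len, strata.values())) == len(exs)

    def test_missing_aux_raises(self):
        with pytest.raises(ValueError):
            stratify([_example(0.5)], "difficulty", {})


class TestPairedTtest:
    def test_identical_vectors_give_half(self):
        assert paired_onesided_ttest([0.9, 0.8, 0.7], [0.9, 0.8, 0.7]) == 0.5

    def test_constant_positive_shift_floors_at_zero(self):
        a = [0.95, 0.96, 0.97]
        b = [0.90, 0.91, 0.92]
        assert paired_onesided_ttest(a, b) == 0.0

    def test_matches_t_distribution_cdf_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.9, 0.05, 12)
        b = rng.normal(0.85, 0.05, 12)
        d = a - b
        t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        expected = 1 - sstats.t.cdf(t, df=len(d) - 1)
        assert paired_onesided_ttest(a, b) == pytest.approx(expected, rel=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_onesided_ttest([1.0], [0.5])

    def test_significance_stars(self):
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.0005) == "**"
        assert significance_stars(0.2) == ""
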