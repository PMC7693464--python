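"""Metric formulas, fold aggregation, ROC/AUC and the Ryan comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nirsclench.classifier import PredictionSet
from nirsclench.evaluation import (ConfusionCounts, EvaluationError,
                                   aggregate_folds, auc_pairwise,
                                   compute_metrics, confusion_counts, f_value,
                                   metrics_report, micro_accuracy, roc_auc,
                                   ryan_compare)
from reference_tables import AGGREGATE_ROWS, GROUP_ROWS, POOLED_COUNTS


def _preds(labels, preds=None, scores=None):
    n = len(labels)
    preds = preds if preds is not None else labels
    scores = scores if scores is not None else [
        0.9 if p == "clench" else 0.1 for p in preds]
    return PredictionSet(pd.DataFrame({
        "subject": ["s"] * n, "modality": ["oxy"] * n, "fold": [0] * n,
        "label": labels, "pred": preds, "score": scores}))


class TestConfusion:
    def test_all_correct(self):
        c = confusion_counts(_preds(["rest"] * 10 + ["clench"] * 10))
        assert (c.tn, c.fp, c.fn, c.tp) == (10, 0, 0, 10)

    def test_all_predicted_clench(self):
        c = confusion_counts(_preds(["rest"] * 10 + ["clench"] * 10,
                                    preds=["clench"] * 20))
        assert (c.tn, c.fp, c.fn, c.tp) == (0, 10, 0, 10)

    def test_brute_force_tally(self):
        labels = ["rest"] * 10 + ["clench"] * 10
        preds = (["rest"] * 8 + ["clench"] * 2 + ["rest"] * 1 + ["clench"] * 9)
        c = confusion_counts(_preds(labels, preds=preds))
        assert (c.tn, c.fp, c.fn, c.tp) == (8, 2, 1, 9)


class TestMetrics:
    def test_five_formulas_on_toy_counts(self):
        m = compute_metrics(ConfusionCounts(tn=8, fp=2, fn=1, tp=9))
        row = m.as_percent_row()
        assert row == {"accuracy": 85.0, "recall": 90.0, "specificity": 80.0,
                       "precision": 81.8, "f_value": 0.857}

    def test_symmetric_counts_give_fifty_percent(self):
        m = compute_metrics(ConfusionCounts(5, 5, 5, 5))
        assert m.accuracy == m.recall == m.specificity == 0.5

    def test_f_from_reference_recall_precision(self):
        assert f_value(97.3, 99.5) / 100 == pytest.approx(0.984, abs=0.001)

    def test_undefined_metric_flagged_not_zero(self):
        m = compute_metrics(ConfusionCounts(tn=5, fp=0, fn=5, tp=0))
        assert math.isnan(m.precision) and math.isnan(m.f_value)
        assert m.specificity == 1.0

    def test_balanced_accuracy_identity(self):
        """On balanced test sets accuracy = (recall + specificity) / 2."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            tp = int(rng.integers(0, 51))
            tn = int(rng.integers(0, 51))
            m = compute_metrics(ConfusionCounts(tn=tn, fp=50 - tn,
                                                fn=50 - tp, tp=tp))
            assert m.accuracy == pytest.approx((m.recall + m.specificity) / 2)


class TestAggregation:
    @pytest.mark.parametrize("modality", ["oxy", "deoxy", "od"])
    def test_macro_mean_sd_reproduce_reference_rows(self, modality):
        rows = np.array(GROUP_ROWS[modality])
        for j, (mean_ref, sd_ref) in enumerate(AGGREGATE_ROWS[modality]):
            tol = 0.001 if j == 4 else 0.1
            assert rows[:, j].mean() == pytest.approx(mean_ref, abs=tol)
            assert rows[:, j].std(ddof=1) == pytest.approx(sd_ref, abs=tol)

    def test_identical_folds_sd_zero(self):
        m = compute_metrics(ConfusionCounts(8, 2, 1, 9))
        agg = aggregate_folds([m, m, m])
        assert all(sd == pytest.approx(0.0, abs=1e-12) for _, sd in agg.values())

    def test_report_table_shape(self):
        m = compute_metrics(ConfusionCounts(8, 2, 1, 9))
        rep = metrics_report([m, m])
        assert list(rep["group"]) == ["Group A", "Group B", "Average", "SD"]

    def test_micro_differs_from_macro_but_pools_counts(self):
        c1 = ConfusionCounts(90, 10, 0, 0)   # 100 images, 90% correct
        c2 = ConfusionCounts(0, 0, 5, 5)     # 10 images, 50% correct
        micro = micro_accuracy([c1, c2])
        assert micro == pytest.approx(95 / 110)
        macro = (compute_metrics(c1).accuracy + compute_metrics(c2).accuracy) / 2
        assert micro != pytest.approx(macro)


class TestROC:
    def test_perfect_separation_auc_one(self):
        p = _preds(["rest"] * 5 + ["clench"] * 5,
                   scores=[0.1] * 5 + [0.9] * 5)
        r = roc_auc(p)
        assert r.auc == 1.0
        assert r.fpr[0] == 0.0 and r.tpr[-1] == 1.0

    def test_toy_set_matches_pairwise_count(self):
        p = _preds(["rest", "rest", "clench", "clench"],
                   scores=[0.1, 0.4, 0.35, 0.8])
        r = roc_auc(p)
        assert r.auc == pytest.approx(0.75)  # 3 of 4 pairs ordered correctly
        assert r.auc == pytest.approx(auc_pairwise([0.35, 0.8], [0.1, 0.4]))

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(1)
        n = 2000
        labels = ["rest"] * n + ["clench"] * n
        scores = rng.uniform(size=2 * n)
        r = roc_auc(_preds(labels, scores=list(scores)))
        assert abs(r.auc - 0.5) < 0.03
        assert r.p_value > 0.01

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 15), st.integers(2, 15))
    def test_auc_equals_brute_force_u_statistic(self, seed, n_pos, n_neg):
        rng = np.random.default_rng(seed)
        pos = rng.choice(np.linspace(0, 1, 11), size=n_pos)  # ties likely
        neg = rng.choice(np.linspace(0, 1, 11), size=n_neg)
        p = _preds(["rest"] * n_neg + ["clench"] * n_pos,
                   scores=list(neg) + list(pos))
        assert roc_auc(p).auc == pytest.approx(auc_pairwise(pos, neg))

    def test_ci_contains_auc_and_is_ordered(self):
        rng = np.random.default_rng(2)
        scores = np.concatenate([rng.uniform(0, 0.8, 100),
                                 rng.uniform(0.2, 1.0, 100)])
        r = roc_auc(_preds(["rest"] * 100 + ["clench"] * 100,
                           scores=list(scores)))
        assert r.ci_low <= r.auc <= r.ci_high

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_auc(_preds(["rest"] * 5, scores=[0.2] * 5))


class TestRyan:
    def test_identical_proportions_not_significant(self):
        decisions = ryan_compare({"a": (500, 1000), "b": (500, 1000)})
        assert not decisions[0].significant

    def test_reference_network_counts_significant(self):
        decisions = ryan_compare(POOLED_COUNTS)
        by_pair = {frozenset((d.name_a, d.name_b)): d for d in decisions}
        od_deoxy = by_pair[frozenset(("od", "deoxy"))]
        od_oxy = by_pair[frozenset(("od", "oxy"))]
        assert od_deoxy.significant and od_deoxy.p_raw < 0.001
        assert od_oxy.significant and od_oxy.p_raw < 0.001

    def test_stepwise_blocking_inside_nonsignificant_span(self):
        counts = {"a": (500, 1000), "b": (501, 1000), "c": (502, 1000)}
        decisions = ryan_compare(counts)
        widest = next(d for d in decisions if d.span == 3)
        assert not widest.significant
        assert all(not d.significant for d in decisions)
        nested = [d for d in decisions if d.span == 2]
        assert all(math.isnan(d.p_raw) for d in nested)  # blocked, untested

    def test_adjusted_level_formula(self):
        decisions = ryan_compare({"a": (10, 100), "b": (50, 100),
                                  "c": (90, 100)}, alpha=0.05)
        for d in decisions:
            assert d.alpha_adjusted == pytest.approx(2 * 0.05 / (3 * d.span))

    def test_invalid_counts_rejected(self):
        with pytest.raises(EvaluationError):
            ryan_compare({"a": (5, 0), "b": (1, 10)})
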