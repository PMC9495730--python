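"""Evaluation tests: confusion matrices, one-vs-rest metrics, CV splits.

The macro-summary cases pin the reporting conventions (sample SD with n-1,
half-up display rounding) against published per-class values whose printed
mean ± SD rows are known.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renalmil import evaluation
from renalmil.evaluation import (
    confusion_matrix,
    kfold_split,
    loso_split,
    macro_summary,
    per_class_metrics,
    round_half_up,
)
from renalmil.fusion import INDETERMINATE
from renalmil.io import SlideRecord


def _records(n_per_class, classes=("A", "B"), subjects=None):
    out = []
    i = 0
    for cls in classes:
        for j in range(n_per_class):
            subject = subjects[i] if subjects else f"subj{i}"
            out.append(SlideRecord(f"slide{i}", subject, f"{i}.png", cls))
            i += 1
    return out


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion_matrix(["A", "B", "A"], ["A", "B", "A"], ["A", "B"])
        np.testing.assert_array_equal(cm.counts, [[2, 0], [0, 1]])
        metrics = per_class_metrics(cm)
        assert all(m["accuracy"] == 100.0 for m in metrics.values())

    def test_counts_by_actual_row_predicted_column(self):
        cm = confusion_matrix(["A", "A", "B"], ["A", "B", "B"], ["A", "B"])
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 1]])

    def test_empty_inputs_give_zero_matrix(self):
        cm = confusion_matrix([], [], ["A", "B"])
        assert cm.counts.sum() == 0 and cm.total == 0

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["A"], ["Z"], ["A", "B"])
        with pytest.raises(ValueError):
            confusion_matrix(["Z"], ["A"], ["A", "B"])

    def test_indeterminate_predictions_counted_separately(self):
        cm = confusion_matrix(["A", "A", "B"], ["A", INDETERMINATE, "B"], ["A", "B"])
        assert cm.n_indeterminate.tolist() == [1, 0]
        assert cm.total == 3
        m = per_class_metrics(cm)
        # the indeterminate A slide is a miss for A: sensitivity 1/2
        assert m["A"]["sensitivity"] == 50.0
        # and correctly-not-B for B: specificity stays perfect
        assert m["B"]["specificity"] == 100.0


class TestPerClassMetrics:
    def test_hand_computed_two_class_example(self):
        # rows A:(8,2), B:(1,9) -> class A: TP=8 FN=2 FP=1 TN=9
        cm = confusion_matrix(
            ["A"] * 10 + ["B"] * 10,
            ["A"] * 8 + ["B"] * 2 + ["A"] * 1 + ["B"] * 9,
            ["A", "B"],
        )
        m = per_class_metrics(cm)["A"]
        assert m["sensitivity"] == 80.0
        assert m["specificity"] == 90.0
        assert m["accuracy"] == 85.0

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.integers(0, 30), min_size=4, max_size=4))
    def test_two_class_sensitivity_specificity_duality(self, counts):
        a_a, a_b, b_a, b_b = counts
        actual = ["A"] * (a_a + a_b) + ["B"] * (b_a + b_b)
        predicted = ["A"] * a_a + ["B"] * a_b + ["A"] * b_a + ["B"] * b_b
        if not actual:
            return
        m = per_class_metrics(confusion_matrix(actual, predicted, ["A", "B"]))
        if m["A"]["sensitivity"] is not None:
            assert m["A"]["sensitivity"] == pytest.approx(m["B"]["specificity"])

    def test_class_without_positives_is_flagged(self):
        cm = confusion_matrix(["A", "A"], ["A", "B"], ["A", "B"])
        m = per_class_metrics(cm)
        assert m["B"]["sensitivity"] is None
        assert "no_positives" in m["B"]["flags"]

    def test_tp_tn_fp_fn_partition_total(self):
        cm = confusion_matrix(
            ["A", "B", "C", "A", "C", "B"], ["B", "B", "C", "A", "A", "C"], ["A", "B", "C"]
        )
        n = cm.total
        for i, cls in enumerate(cm.classes):
            tp = cm.counts[i, i]
            fn = cm.counts[i].sum() - tp
            fp = cm.counts[:, i].sum() - tp
            tn = n - tp - fn - fp
            assert tp + tn + fp + fn == n


class TestMacroSummary:
    @pytest.mark.parametrize(
        "values, mean, sd",
        [
            # published per-class rows whose mean ± sample SD are known
            ((89.0, 92.8, 90.3, 100.0), 93.0, 4.9),  # patch-level accuracy
            ((87.7, 99.8, 77.7, 100.0), 91.3, 10.7),  # patch-level sensitivity
            ((93.1, 89.5, 99.9, 100.0), 95.6, 5.2),  # patch-level specificity
            ((92.0, 93.3, 85.7, 100.0), 92.8, 5.9),  # slide-level accuracy
            ((84.0, 66.7, 71.4, 80.0), 75.5, 7.9),  # slide-level comparison row
        ],
    )
    def test_published_summary_rows_reproduced(self, values, mean, sd):
        s = macro_summary(list(values))
        assert s.rounded(1) == (mean, sd)

    def test_fold_mean_reproduced_to_two_decimals(self):
        # five fold accuracies of the fused classifier; printed mean 93.76
        folds = [99.77, 97.42, 87.42, 95.52, 88.66]
        assert round_half_up(float(np.mean(folds)), 2) == 93.76

    def test_matches_independent_mean_sd(self, rng):
        vals = rng.uniform(50, 100, size=6).tolist()
        s = macro_summary(vals)
        assert s.mean == pytest.approx(sum(vals) / 6, abs=1e-9)
        manual_sd = (sum((v - s.mean) ** 2 for v in vals) / 5) ** 0.5
        assert s.sd == pytest.approx(manual_sd, abs=1e-9)

    def test_constant_values_have_zero_sd(self):
        s = macro_summary([88.8] * 4)
        assert s.mean == 88.8 and s.sd == 0.0

    def test_single_value_flagged(self):
        s = macro_summary([90.0])
        assert s.sd == 0.0 and "single_value" in s.flags

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            macro_summary([])

    def test_half_up_rounding_convention(self):
        assert round_half_up(92.75, 1) == 92.8
        assert round_half_up(92.65, 1) == 92.7
        assert round_half_up(-1.25, 1) == -1.3


class TestCVSplits:
    def test_kfold_partitions_all_slides(self):
        records = _records(5)  # 10 slides
        split = kfold_split(records, k=5, seed=1)
        assert len(split) == 5
        seen = []
        for train, test in split:
            assert len(test) == 2
            assert set(train).isdisjoint(test)
            seen += list(test)
        assert sorted(seen) == sorted(r.slide_id for r in records)

    def test_kfold_stratifies_when_possible(self):
        records = _records(4)
        for train, test in kfold_split(records, k=4, seed=0):
            labels = {r.slide_id: r.label for r in records}
            assert sorted(labels[t] for t in test) == ["A", "B"]

    def test_kfold_deterministic_given_seed(self):
        records = _records(5)
        assert kfold_split(records, 5, seed=3).folds == kfold_split(records, 5, seed=3).folds

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(_records(3), k=1)

    def test_loso_one_fold_per_subject_no_leakage(self):
        subjects = ["s1", "s1", "s2", "s3", "s3", "s4"]
        records = _records(3, subjects=subjects)
        split = loso_split(records)
        assert len(split) == 4
        by_slide = {r.slide_id: r.subject_id for r in records}
        for train, test in split:
            test_subjects = {by_slide[t] for t in test}
            assert len(test_subjects) == 1
            assert test_subjects.isdisjoint({by_slide[t] for t in train})

    def test_loso_requires_subject_ids(self):
        records = [SlideRecord("a", None, "a.png", "A")]
        with pytest.raises(ValueError):
            loso_split(records)
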