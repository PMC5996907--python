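"""Confusion-matrix metrics, cross-validation harness, rejection curves, ablations."""

import numpy as np
import pandas as pd
import pytest

from dsindex import (
    ConfusionMatrix,
    accuracy,
    ablation,
    balanced_accuracy,
    complete_case_filter,
    generate_cohort,
    kfold_cv,
    pairwise_ablation,
    preset_separable,
    rejection_analysis,
    sensitivities,
    summarize,
)
from dsindex.evaluation import _all_subsets

CLASSES = ["CN", "AD", "FTLD", "DLB", "VaD"]


class TestMetrics:
    def test_identity_matrix_is_perfect(self):
        cm = ConfusionMatrix(["A", "B", "C"], np.eye(3, dtype=int) * 4)
        assert accuracy(cm) == 100.0
        assert balanced_accuracy(cm) == 100.0
        assert all(v == 100.0 for v in sensitivities(cm).values())

    def test_all_mass_off_diagonal_is_zero(self):
        cm = ConfusionMatrix(["A", "B"], np.array([[0, 3], [5, 0]]))
        assert accuracy(cm) == 0.0
        assert balanced_accuracy(cm) == 0.0

    def test_balanced_accuracy_undefined_with_empty_row(self):
        cm = ConfusionMatrix(["A", "B"], np.array([[3, 1], [0, 0]]))
        assert balanced_accuracy(cm) is None
        assert np.isnan(sensitivities(cm)["B"])

    def test_empty_matrix_errors(self):
        cm = ConfusionMatrix(["A"], np.zeros((1, 1), dtype=int))
        with pytest.raises(ValueError):
            accuracy(cm)

    def test_accuracy_equals_balanced_accuracy_on_equal_class_sizes(self):
        cm = ConfusionMatrix(["A", "B"], np.array([[8, 2], [3, 7]]))
        assert accuracy(cm) == pytest.approx(balanced_accuracy(cm))

    def test_constant_classifier_on_balanced_cohort_scores_one_over_k(self):
        preds = pd.DataFrame({
            "true": np.repeat(CLASSES, 10),
            "predicted": "AD",
        })
        cm = ConfusionMatrix.from_predictions(preds["true"], preds["predicted"], CLASSES)
        assert balanced_accuracy(cm) == pytest.approx(100.0 / 5)

    def test_row_sums_match_per_class_counts(self):
        cm = ConfusionMatrix.from_predictions(
            ["A", "A", "B"], ["A", "B", "B"], ["A", "B"])
        assert cm.row_sums().tolist() == [2, 1]
        assert cm.total == 3


class TestKFoldCV:
    def test_every_subject_predicted_exactly_once(self, small_cohort, small_study_config):
        preds = kfold_cv(small_cohort, small_study_config, k=5, seed=0)
        assert len(preds) == len(small_cohort)
        assert preds["subject_id"].is_unique

    def test_same_seed_reproduces_fold_assignment_and_predictions(
            self, small_cohort, small_study_config):
        a = kfold_cv(small_cohort, small_study_config, k=5, seed=3)
        b = kfold_cv(small_cohort, small_study_config, k=5, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_stratification_keeps_all_classes_in_each_fold(
            self, small_cohort, small_study_config):
        preds = kfold_cv(small_cohort, small_study_config, k=5, seed=1)
        per_fold = preds.groupby("fold")["true"].nunique()
        assert (per_fold == 5).all()  # 20 per class, k=5 -> 4 of each per fold

    def test_k_larger_than_smallest_class_errors(self, small_cohort, small_study_config):
        with pytest.raises(ValueError, match="smaller k"):
            kfold_cv(small_cohort, small_study_config, k=25, seed=0)

    def test_full_cohort_normalization_option_runs(self, small_cohort, small_study_config):
        preds = kfold_cv(small_cohort, small_study_config, k=5, seed=0,
                         per_fold_normalization=False)
        assert len(preds) == len(small_cohort)

    def test_modality_restriction_prunes_features(self, small_cohort, small_study_config):
        preds = kfold_cv(small_cohort, small_study_config, k=5, seed=0,
                         modalities=("VMRI",))
        res = summarize(preds, CLASSES)
        assert 0 <= res["accuracy"] <= 100


@pytest.fixture(scope="module")
def predictions(small_cohort, small_study_config):
    return kfold_cv(small_cohort, small_study_config, k=5, seed=2)


class TestRejection:
    def test_zero_fraction_reproduces_full_cohort_metrics(self, predictions):
        curve = rejection_analysis(predictions, [0.0], CLASSES)
        point = curve.points[0]
        full = summarize(predictions, CLASSES)
        assert point.accuracy == pytest.approx(full["accuracy"])
        assert point.cutoff == pytest.approx(predictions["confidence"].min())
        assert point.n_retained == len(predictions)

    def test_counts_conserved_and_cutoffs_non_decreasing(self, predictions):
        fracs = [0.0, 0.25, 0.5, 0.75]
        curve = rejection_analysis(predictions, fracs, CLASSES)
        totals = predictions["true"].value_counts()
        cutoffs = [p.cutoff for p in curve.points]
        assert cutoffs == sorted(cutoffs)
        for point in curve.points:
            for c in CLASSES:
                left_out = totals[c] - point.retained_per_class[c]
                assert 0 <= left_out <= totals[c]
                assert point.left_out_percent[c] == pytest.approx(
                    100.0 * left_out / totals[c])
        retained = np.array([[p.retained_per_class[c] for c in CLASSES]
                             for p in curve.points])
        assert (np.diff(retained, axis=0) <= 0).all()

    def test_retained_count_uses_ceiling(self, predictions):
        n = len(predictions)
        curve = rejection_analysis(predictions, [0.33], CLASSES)
        assert curve.points[0].n_retained == int(np.ceil(0.67 * n))

    def test_confidence_ties_broken_by_subject_id(self, predictions):
        tied = predictions.copy()
        tied["confidence"] = 0.5
        a = rejection_analysis(tied, [0.5], CLASSES).points[0]
        b = rejection_analysis(tied.sample(frac=1, random_state=0), [0.5], CLASSES).points[0]
        assert a.retained_per_class == b.retained_per_class

    def test_invalid_fraction_errors(self, predictions):
        with pytest.raises(ValueError):
            rejection_analysis(predictions, [1.0], CLASSES)

    def test_accuracy_improves_with_rejection_on_noisy_separable_data(self):
        config = preset_separable(1.5, class_sizes={c: 30 for c in CLASSES}, seed=5)
        cohort, _ = generate_cohort(config)
        preds = kfold_cv(cohort, config.study_config(), k=5, seed=5)
        curve = rejection_analysis(preds, [0.0, 0.5], CLASSES)
        assert curve.points[1].accuracy >= curve.points[0].accuracy


class TestAblation:
    def test_four_modalities_give_fifteen_subsets(self):
        assert len(_all_subsets(["NP", "CSF", "VMRI", "AMRI"])) == 15

    def test_restricted_subset_evaluated(self, small_cohort, small_study_config):
        table = ablation(small_cohort, small_study_config,
                         subsets=[("NP",), ("NP", "CSF")], k=5, seed=0)
        assert table["feature_set"].tolist() == ["NP", "NP+CSF"]
        assert table["balanced_accuracy"].between(0, 100).all()

    def test_empty_subset_errors(self, small_cohort, small_study_config):
        with pytest.raises(ValueError, match="empty"):
            ablation(small_cohort, small_study_config, subsets=[()], k=5)

    def test_pairwise_mode_covers_all_class_pairs(self, small_cohort, small_study_config):
        table = pairwise_ablation(small_cohort, small_study_config,
                                  subsets=[("NP", "CSF", "VMRI", "AMRI")], k=5, seed=0)
        pair_cols = [c for c in table.columns if "_vs_" in c]
        assert len(pair_cols) == 10  # C(5, 2)


class TestCompleteCase:
    def test_no_missing_data_is_identity(self):
        frame = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        out = complete_case_filter(frame, ["a", "b"])
        pd.testing.assert_frame_equal(out, frame)

    def test_subject_missing_one_named_feature_dropped(self):
        frame = pd.DataFrame({"a": [1.0, np.nan], "b": [3.0, 4.0]})
        out = complete_case_filter(frame, ["a"])
        assert len(out) == 1

    def test_empty_feature_set_is_identity(self):
        frame = pd.DataFrame({"a": [np.nan]})
        assert len(complete_case_filter(frame, [])) == 1
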