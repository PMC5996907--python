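"""Total indices, argmax decision, confidence, and multiclass invariants."""

import numpy as np
import pandas as pd
import pytest

from dsindex import DSIClassifier, classify, generate_cohort, preset_separable, total_index

CLASSES = ["CN", "AD", "FTLD", "DLB", "VaD"]


def _scores_for(i, values):
    others = [c for c in CLASSES if c != i]
    return {(i, j): v for j, v in zip(others, values)}


class TestTotalIndex:
    def test_unanimous_pairwise_agreement_gives_one(self):
        scores = _scores_for("AD", [1.0] * 4)
        assert total_index(scores, "AD", 5, mode="pairs") == pytest.approx(1.0)

    @pytest.mark.parametrize("mode, expected", [("pairs", 0.5), ("classes", 0.4)])
    def test_uninformative_scores(self, mode, expected):
        scores = _scores_for("AD", [0.5] * 4)
        assert total_index(scores, "AD", 5, mode=mode) == pytest.approx(expected)

    def test_mean_of_four(self):
        scores = _scores_for("CN", [0.9, 0.8, 0.7, 0.6])
        assert total_index(scores, "CN", 5, mode="pairs") == pytest.approx(0.75)

    def test_missing_pairwise_score_errors(self):
        scores = _scores_for("CN", [0.9, 0.8, 0.7, 0.6])
        del scores[("CN", "VaD")]
        with pytest.raises(ValueError, match="expected 4"):
            total_index(scores, "CN", 5)

    def test_priors_weight_the_competitors(self):
        scores = {("A", "B"): 1.0, ("A", "C"): 0.0}
        assert total_index(scores, "A", 3, priors={"B": 3.0, "C": 1.0}) == pytest.approx(0.75)


class TestClassify:
    def test_argmax_and_confidence(self):
        indices = {"CN": 0.9, "AD": 0.3, "FTLD": 0.3, "DLB": 0.3, "VaD": 0.3}
        assert classify(indices, CLASSES) == ("CN", 0.9)

    def test_all_tied_first_class_wins(self, caplog):
        indices = {c: 0.5 for c in CLASSES}
        cls, conf = classify(indices, CLASSES)
        assert (cls, conf) == ("CN", 0.5)

    def test_interior_maximum(self):
        indices = {"CN": 0.2, "AD": 0.81, "FTLD": 0.6, "DLB": 0.4, "VaD": 0.1}
        assert classify(indices, CLASSES) == ("AD", 0.81)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            classify({})


class TestTraining:
    def test_five_classes_give_twenty_ordered_pair_models(
            self, small_cohort, small_study_config):
        clf = DSIClassifier(hierarchy=small_study_config.hierarchy, classes=CLASSES,
                            vascular_class="VaD")
        clf.fit(small_cohort, small_cohort["diagnosis"])
        assert len(clf.pairwise_models_) == 20

    def test_missing_class_errors_with_class_name(self, small_cohort, small_study_config):
        sub = small_cohort[small_cohort["diagnosis"] != "DLB"]
        clf = DSIClassifier(hierarchy=small_study_config.hierarchy, classes=CLASSES)
        with pytest.raises(ValueError, match="DLB"):
            clf.fit(sub, sub["diagnosis"])

    def test_two_class_total_indices_are_complementary(self, small_cohort,
                                                       small_study_config):
        sub = small_cohort[small_cohort["diagnosis"].isin(["CN", "AD"])]
        clf = DSIClassifier(hierarchy=small_study_config.hierarchy, classes=["CN", "AD"])
        clf.fit(sub, sub["diagnosis"])
        indices = clf.decision_function(sub)
        np.testing.assert_allclose(indices.sum(axis=1), 1.0, atol=1e-12)


@pytest.fixture(scope="module")
def fitted(small_cohort, small_study_config):
    clf = DSIClassifier(hierarchy=small_study_config.hierarchy, classes=CLASSES,
                        vascular_class="VaD")
    return clf.fit(small_cohort, small_cohort["diagnosis"])


class TestPredictions:
    def test_total_indices_in_unit_interval(self, fitted, small_cohort):
        indices = fitted.decision_function(small_cohort)
        assert indices.min() >= 0 and indices.max() <= 1

    def test_classes_mode_caps_at_k_minus_one_over_k(self, small_cohort,
                                                     small_study_config):
        clf = DSIClassifier(hierarchy=small_study_config.hierarchy, classes=CLASSES,
                            normalization="classes", vascular_class="VaD")
        clf.fit(small_cohort, small_cohort["diagnosis"])
        indices = clf.decision_function(small_cohort)
        assert indices.max() <= 0.8 + 1e-12

    def test_ordered_pair_scores_sum_to_k_choose_2(self, fitted, small_cohort):
        """Each unordered pair contributes DSI(i,j) + DSI(j,i) = 1 exactly."""
        scores, _ = fitted.pairwise_scores(small_cohort.head(30))
        total = sum(scores.values())
        np.testing.assert_allclose(total, 10.0, atol=1e-10)  # K(K-1)/2 for K=5

    def test_all_missing_subject_ties_to_first_class_and_flags(self, fitted,
                                                               small_cohort):
        empty = small_cohort.head(1).copy()
        feature_cols = fitted.hierarchy.feature_names
        empty[feature_cols] = np.nan
        table = fitted.predict_table(empty)
        assert table.loc[0, "predicted"] == "CN"  # first in configured order
        assert table.loc[0, "confidence"] == pytest.approx(0.5)
        assert bool(table.loc[0, "flag_no_features"])

    def test_confidence_is_max_total_index_and_predicted_attains_it(
            self, fitted, small_cohort):
        table = fitted.predict_table(small_cohort)
        indices = table[[f"dsi_{c}" for c in CLASSES]].to_numpy()
        np.testing.assert_allclose(table["confidence"], indices.max(axis=1))
        argmax_class = np.array(CLASSES, dtype=object)[indices.argmax(axis=1)]
        assert (table["predicted"].to_numpy() == argmax_class).all()

    def test_centroid_subject_of_separated_class_recovered(self, small_study_config):
        config = preset_separable(8.0, class_sizes={c: 15 for c in CLASSES}, seed=3)
        cohort, _ = generate_cohort(config)
        clf = DSIClassifier(hierarchy=config.hierarchy(), classes=CLASSES,
                            vascular_class="VaD")
        clf.fit(cohort, cohort["diagnosis"])
        probe = cohort[cohort["diagnosis"] == "FTLD"].head(5)
        assert (clf.predict(probe) == "FTLD").all()

    def test_branch_contributions_cover_modalities_in_unit_interval(
            self, fitted, small_cohort):
        branches = fitted.branch_contributions(small_cohort.head(20))
        assert set(branches.columns) == {"NP", "CSF", "VMRI", "AMRI"}
        vals = branches.to_numpy()
        seen = ~np.isnan(vals)
        assert seen.any()
        assert (vals[seen] >= 0).all() and (vals[seen] <= 1).all()

    def test_permuting_class_order_permutes_predictions(self, small_cohort,
                                                        small_study_config):
        permuted = ["VaD", "FTLD", "CN", "AD", "DLB"]
        a = DSIClassifier(hierarchy=small_study_config.hierarchy, classes=CLASSES,
                          vascular_class="VaD").fit(small_cohort, small_cohort["diagnosis"])
        b = DSIClassifier(hierarchy=small_study_config.hierarchy, classes=permuted,
                          vascular_class="VaD").fit(small_cohort, small_cohort["diagnosis"])
        # continuous features: ties have probability zero, so predictions agree
        assert (a.predict(small_cohort) == b.predict(small_cohort)).all()


def test_sklearn_get_set_params_round_trip(small_study_config):
    clf = DSIClassifier(hierarchy=small_study_config.hierarchy, classes=CLASSES)
    params = clf.get_params()
    clone = DSIClassifier(**params)
    assert clone.get_params()["classes"] == CLASSES
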