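"""Leave-one-patient-out harness and the classifier adapters."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from relapsemri.evaluation import (
    DEFAULT_BANK,
    ClassifierSpec,
    EvaluationError,
    PooledPinvLDA,
    compare_classifiers,
    evaluate,
    lopo_folds,
    pool_folds,
    train_and_predict,
)
from relapsemri.schema import PROGRESSIVE, RESPONSIVE
from relapsemri.simulate import SimulationConfig, generate_cohort, simulate_cohort

NO_MISSING = {"spectroscopy": 0.0, "perfusion": 0.0, "diffusion": 0.0}


def small_cohort(seed=0, delta=3.0, n=8, missingness=NO_MISSING):
    return simulate_cohort(
        SimulationConfig(
            seed=seed,
            n_patients=n,
            class_separation=delta,
            missingness=dict(missingness),
        )
    )


class TestClassifierSpec:
    def test_unknown_family_rejected(self):
        with pytest.raises(EvaluationError):
            ClassifierSpec("nearest_centroid")

    def test_unknown_svm_kernel_rejected(self):
        with pytest.raises(EvaluationError):
            ClassifierSpec("svm", "wavelet")

    def test_scaling_applies_to_margin_and_distance_families(self):
        assert ClassifierSpec("svm", "linear").standardize
        assert ClassifierSpec("knn").standardize
        assert not ClassifierSpec("random_forest").standardize

    def test_robust_boost_marked_as_substitution(self):
        spec = next(s for s in DEFAULT_BANK if s.variant == "robustboost")
        assert spec.substituted


class TestPooledPinvLDA:
    def test_matches_reference_lda_when_covariance_invertible(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(0, 1, (60, 5)), rng.normal(1.5, 1, (60, 5))]
        )
        y = np.array(["a"] * 60 + ["b"] * 60)
        ours = PooledPinvLDA().fit(X, y)
        ref = LinearDiscriminantAnalysis(solver="svd").fit(X, y)
        X_new = rng.normal(0.75, 1, (200, 5))
        agreement = np.mean(ours.predict(X_new) == ref.predict(X_new))
        assert agreement > 0.98

    def test_survives_singular_covariance(self):
        # fewer samples than features: pooled covariance is rank-deficient
        # and only the pseudoinverse keeps the discriminant defined
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (10, 27))
        X[5:] += 3.0
        y = np.array(["a"] * 5 + ["b"] * 5)
        model = PooledPinvLDA().fit(X, y)
        assert set(model.predict(X)) <= {"a", "b"}
        assert (model.predict(X) == y).mean() >= 0.8

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            PooledPinvLDA().fit(np.zeros((4, 2)), np.array(["a"] * 4))


class TestLopoFolds:
    def test_one_fold_per_patient(self):
        cohort = small_cohort(n=5)
        folds = lopo_folds(cohort)
        assert len(folds) == 5
        assert {p.patient_id for _, p in folds} == {
            p.patient_id for p in cohort.patients
        }

    def test_training_cohort_excludes_test_patient(self):
        for train, test in lopo_folds(small_cohort(n=5)):
            assert test.patient_id not in {
                p.patient_id for p in train.patients
            }
            assert len(train.patients) == 4

    def test_single_patient_rejected(self):
        cohort = small_cohort(n=5)
        cohort.patients = cohort.patients[:1]
        with pytest.raises(EvaluationError):
            lopo_folds(cohort)


class TestTrainAndPredict:
    def test_separable_classes_predicted_correctly(self):
        cohort = small_cohort(delta=4.0)
        train, test = lopo_folds(cohort)[0]
        from relapsemri.cohort import select_complete

        result = train_and_predict(
            ClassifierSpec("svm", "linear"), select_complete(train), test
        )
        assert result.predictions
        assert all(p == test.decision_class for _, _, p in result.predictions)

    def test_no_eligible_session_gives_empty_fold(self):
        cohort = small_cohort()
        train, test = lopo_folds(cohort)[0]
        from relapsemri.cohort import select_complete

        for tp in test.timepoints:  # mask everything maskable
            tp.missing_mask[3:25] = True
        result = train_and_predict(
            ClassifierSpec("svm", "linear"), select_complete(train), test
        )
        assert result.predictions == []

    def test_one_class_training_rejected(self):
        cohort = small_cohort()
        train, test = lopo_folds(cohort)[0]
        for p in train.patients:
            p.decision_class = PROGRESSIVE
            for tp in p.timepoints:
                if tp.label != "unlabeled":
                    tp.label = PROGRESSIVE
        from relapsemri.cohort import select_complete

        with pytest.raises(EvaluationError, match="single class"):
            train_and_predict(
                ClassifierSpec("svm", "linear"), select_complete(train), test
            )

    def test_pool_folds_counts_patients_per_offset(self):
        from relapsemri.evaluation import FoldResult

        folds = [
            FoldResult("a", [(0, PROGRESSIVE, PROGRESSIVE)]),
            FoldResult("b", [(0, RESPONSIVE, PROGRESSIVE), (-1, RESPONSIVE, RESPONSIVE)]),
        ]
        series = pool_folds(folds)
        assert series.entries[0] == (0.5, 2)
        assert series.entries[-1] == (0.0, 1)


class TestEvaluate:
    def test_deterministic_given_seed(self):
        cohort = small_cohort(seed=2, missingness={"spectroscopy": 0.3,
                                                   "perfusion": 0.2,
                                                   "diffusion": 0.2})
        spec = ClassifierSpec("random_forest")
        a = evaluate(cohort, spec, variant="imputed", seed=9)
        b = evaluate(cohort, spec, variant="imputed", seed=9)
        assert a.wber == b.wber
        assert a.series.entries == b.series.entries

    def test_separated_cohort_scores_zero_at_decision(self):
        cohort = small_cohort(seed=3, delta=4.0, n=10)
        report = evaluate(cohort, ClassifierSpec("random_forest"), seed=1)
        assert report.series.entries[0][0] == 0.0

    def test_complete_variant_covers_only_complete_offsets(self):
        cohort = small_cohort(
            seed=6, n=12,
            missingness={"spectroscopy": 0.3, "perfusion": 0.2, "diffusion": 0.2},
        )
        report = evaluate(cohort, ClassifierSpec("dlda"), variant="complete",
                          seed=1)
        complete_offsets = {
            tp.offset
            for tp in cohort.iter_timepoints()
            if not tp.missing_mask.any()
        }
        assert set(report.series.entries) <= complete_offsets

    def test_imputed_variant_covers_every_offset(self):
        cohort = small_cohort(
            seed=5, n=12,
            missingness={"spectroscopy": 0.6, "perfusion": 0.3, "diffusion": 0.4},
        )
        report = evaluate(cohort, ClassifierSpec("dlda"), variant="imputed",
                          seed=1)
        all_offsets = {tp.offset for tp in cohort.iter_timepoints()}
        assert set(report.series.entries) == all_offsets

    def test_modality_subset_evaluation_runs(self):
        cohort = small_cohort(seed=6)
        report = evaluate(
            cohort, ClassifierSpec("dlda"), features="perfusion", seed=1
        )
        assert report.features == "perfusion"
        assert 0.0 <= report.wber <= 1.0

    def test_wber_decreases_with_separation_in_expectation(self):
        """Parameter recovery: larger class separation, lower weighted BER."""
        means = []
        for delta in (0.0, 1.5, 3.0):
            wbers = []
            for seed in range(20):
                cohort = generate_cohort(
                    SimulationConfig(
                        seed=seed, n_patients=10, class_separation=delta,
                        missingness=dict(NO_MISSING),
                    )
                )
                wbers.append(
                    evaluate(cohort, ClassifierSpec("dlda"), seed=seed).wber
                )
            means.append(np.mean(wbers))
        assert means[0] > means[1] > means[2]


class TestCompareClassifiers:
    def test_two_spec_layout(self):
        cohort = small_cohort(seed=7, missingness={"spectroscopy": 0.3,
                                                   "perfusion": 0.2,
                                                   "diffusion": 0.2})
        specs = [ClassifierSpec("dlda"), ClassifierSpec("svm", "linear")]
        table = compare_classifiers(cohort, specs, seed=1, mark_best=1)
        assert list(table.columns) == ["complete", "imputed", "average", "best"]
        assert list(table.index) == ["dlda", "svm-linear"]
        np.testing.assert_allclose(
            table["average"], (table["complete"] + table["imputed"]) / 2
        )
        assert table["best"].sum() == 1

    def test_single_spec(self):
        cohort = small_cohort(seed=7, missingness={"spectroscopy": 0.3,
                                                   "perfusion": 0.2,
                                                   "diffusion": 0.2})
        table = compare_classifiers(cohort, [ClassifierSpec("dlda")], seed=1)
        assert len(table) == 1

    def test_empty_spec_list_rejected(self):
        with pytest.raises(EvaluationError):
            compare_classifiers(small_cohort(), [], seed=1)
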