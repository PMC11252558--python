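"""Feature assembly, RFECV selection, nested-CV SVM, leakage and permutation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from vnspredict.prediction import (
    FeatureTable,
    assemble_features,
    encode_clinical,
    nested_cv_svm,
    permutation_test,
    rfecv_select,
)
from vnspredict.recording import ALPHA_ROI
from vnspredict.synthetic import desk_spec, generate_cohort


def make_feature_table(n=65, n_informative=3, n_noise=5, gap=3.0, seed=0):
    """Separable-by-construction cohort: informative features shifted by
    ``gap`` within-group SDs between classes."""
    rng = np.random.default_rng(seed)
    n_r = int(round(n * 38 / 65))
    y = np.array([1] * n_r + [0] * (n - n_r))
    cols = {}
    for i in range(n_informative):
        cols[f"info_{i}"] = rng.normal(size=n) + gap * y
    for i in range(n_noise):
        cols[f"noise_{i}"] = rng.normal(size=n)
    X = pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])
    labels = pd.Series(np.where(y == 1, "R50", "NR50"), index=X.index)
    return FeatureTable(X=X, labels=labels)


@pytest.fixture(scope="module")
def clinical_cohort():
    return generate_cohort(desk_spec(seed=1, duration=2.0,
                                     n_responders=20, n_nonresponders=15))


class TestEncoding:
    def test_twenty_clinical_columns(self, clinical_cohort):
        enc = encode_clinical(clinical_cohort.clinical)
        assert enc.shape[1] == 20
        assert enc.select_dtypes(exclude="number").empty

    def test_dummy_levels_complete(self, clinical_cohort):
        enc = encode_clinical(clinical_cohort.clinical)
        for col in ("etiology_immune", "syndrome_IS", "mri_focal"):
            assert col in enc.columns
        for ref in ("etiology_structural", "syndrome_unclassified", "mri_negative"):
            assert ref not in enc.columns


class TestAssembly:
    def _sources(self, cohort):
        clin = cohort.clinical.copy()
        clin["label"] = cohort.labels
        rng = np.random.default_rng(0)
        ne = pd.DataFrame(
            rng.uniform(0.1, 0.3, (len(clin), 10)),
            index=clin.index, columns=list(ALPHA_ROI.channels),
        )
        hh = pd.Series(rng.uniform(1.6, 1.8, len(clin)), index=clin.index)
        return clin, ne, hh

    def test_thirty_one_features(self, clinical_cohort):
        clin, ne, hh = self._sources(clinical_cohort)
        ft = assemble_features(clin, ne, hh)
        assert ft.X.shape[1] + len(ft.dropped) == 31

    def test_minmax_normalization(self):
        vals = pd.Series([2.0, 4.0, 6.0])
        ft = FeatureTable(
            X=pd.DataFrame({"f": vals}), labels=pd.Series(["R50", "NR50", "R50"])
        )
        np.testing.assert_allclose(ft.normalized().X["f"], [0, 0.5, 1.0])

    def test_constant_feature_dropped_with_warning(self, clinical_cohort):
        clin, ne, hh = self._sources(clinical_cohort)
        hh[:] = 1.7
        with pytest.warns(UserWarning, match="theta_roi_hhse"):
            ft = assemble_features(clin, ne, hh)
        assert "theta_roi_hhse" in ft.dropped
        assert "theta_roi_hhse" not in ft.X.columns

    def test_subject_mismatch_named(self, clinical_cohort):
        clin, ne, hh = self._sources(clinical_cohort)
        ne = ne.iloc[:-1]
        with pytest.raises(ValueError, match=clin.index[-1]):
            assemble_features(clin, ne, hh)

    def test_correlation_diagnostic_reported(self, clinical_cohort):
        clin, ne, hh = self._sources(clinical_cohort)
        ft = assemble_features(clin, ne, hh)
        assert 0.0 <= ft.max_abs_correlation <= 1.0


class TestRfecv:
    def test_informative_feature_recovered(self):
        hits = 0
        for seed in range(20):
            ft = make_feature_table(
                n=40, n_informative=1, n_noise=9, gap=2.5, seed=seed
            )
            sel = rfecv_select(ft, seed=seed)
            hits += "info_0" in sel["selected"]
        assert hits >= 19

    def test_score_curve_shape(self):
        ft = make_feature_table(n=30, n_informative=2, n_noise=4, seed=3)
        sel = rfecv_select(ft, seed=3)
        assert len(sel["score_curve"]) == 6
        np.testing.assert_array_equal(sel["cardinalities"], np.arange(1, 7))

    def test_score_ties_resolve_to_smallest_cardinality(self):
        # perfectly separable: every cardinality scores 1.0, so the tie-break
        # must choose a single feature
        ft = make_feature_table(n=40, n_informative=4, n_noise=0, gap=50.0, seed=5)
        sel = rfecv_select(ft, seed=0)
        assert np.allclose(sel["score_curve"], 1.0)
        assert sel["n_selected"] == 1

    def test_non_numeric_rejected(self):
        X = pd.DataFrame({"f": ["a", "b", "c", "d"]})
        ft = FeatureTable(X=X, labels=pd.Series(["R50", "NR50"] * 2))
        with pytest.raises(ValueError, match="numeric"):
            rfecv_select(ft)


class TestNestedCv:
    def test_separable_cohort_high_performance(self):
        ft = make_feature_table(seed=0)
        report = nested_cv_svm(ft, seed=0)
        assert report.accuracy >= 0.9
        assert report.auc >= 0.95

    def test_confusion_matrix_internal_consistency(self):
        ft = make_feature_table(seed=1)
        report = nested_cv_svm(ft, seed=1)
        assert report.confusion.sum() == len(ft.labels)
        tn, fp, fn, tp = report.confusion.ravel()
        assert report.precision == pytest.approx(tp / (tp + fp))
        assert report.specificity == pytest.approx(tn / (tn + fp))
        assert report.accuracy == pytest.approx((tp + tn) / (tp + tn + fp + fn))

    def test_permuted_labels_at_chance(self):
        accs = []
        for seed in range(20):
            ft = make_feature_table(n=60, n_informative=0, n_noise=6, seed=seed)
            report = nested_cv_svm(ft, seed=seed, c_grid=(1.0,), outer_folds=5,
                                   inner_folds=3)
            accs.append(report.accuracy)
        majority = 36 / 60  # rounded class split used by the builder
        # mean accuracy over seeds within binomial noise of the majority rate
        assert abs(np.mean(accs) - majority) < 3 * np.sqrt(
            majority * (1 - majority) / (60 * 20)
        ) + 0.05

    def test_determinism(self):
        ft = make_feature_table(seed=2)
        a = nested_cv_svm(ft, seed=5, c_grid=(0.1, 1.0), outer_folds=5, inner_folds=3)
        b = nested_cv_svm(ft, seed=5, c_grid=(0.1, 1.0), outer_folds=5, inner_folds=3)
        assert a.to_dict() == b.to_dict()

    def test_selection_inside_folds_records_features(self):
        ft = make_feature_table(n=40, n_informative=2, n_noise=3, seed=4)
        report = nested_cv_svm(
            ft, seed=4, select=True, outer_folds=4, inner_folds=3, c_grid=(1.0,)
        )
        assert len(report.selected_per_fold) == 4
        assert all(len(s) >= 1 for s in report.selected_per_fold)


class _SpyScaler(BaseEstimator, TransformerMixin):
    """Records the row fingerprints each `fit` sees."""

    calls: list = []

    def fit(self, X, y=None):
        self.lo_ = np.asarray(X).min(axis=0)
        self.hi_ = np.asarray(X).max(axis=0)
        _SpyScaler.calls.append({hash(row.tobytes()) for row in np.asarray(X)})
        return self

    def transform(self, X):
        X = np.asarray(X)
        rng = np.where(self.hi_ > self.lo_, self.hi_ - self.lo_, 1.0)
        return (X - self.lo_) / rng


def test_no_leakage_of_held_out_subjects_into_scaling():
    """Normalization bounds fit inside the cross-validation must never see
    held-out rows: every scaler fit call must miss at least one outer fold."""
    ft = make_feature_table(n=40, seed=6)
    _SpyScaler.calls = []
    factory = lambda: Pipeline([("scale", _SpyScaler()), ("svm", SVC(kernel="linear"))])
    nested_cv_svm(
        ft, seed=6, outer_folds=4, inner_folds=3, c_grid=(1.0,),
        pipeline_factory=factory,
    )
    n = len(ft.labels)
    all_rows = {hash(row.tobytes()) for row in ft.X.to_numpy()}
    max_fit = max(len(c) for c in _SpyScaler.calls)
    assert max_fit <= n - n // 4  # no fit ever saw a full outer fold's test rows
    held_out_seen = set()
    for call in _SpyScaler.calls:
        held_out_seen |= all_rows - call
    assert held_out_seen == all_rows  # every row was excluded somewhere


class TestPermutationTest:
    def test_minimum_permutations_enforced(self):
        ft = make_feature_table(n=30, seed=0)
        with pytest.raises(ValueError, match="100"):
            permutation_test(ft, n_permutations=10)

    def test_null_p_in_add_one_bounds_and_signal_detected(self):
        ft = make_feature_table(n=40, n_informative=3, n_noise=2, gap=3.0, seed=7)
        res = permutation_test(
            ft, n_permutations=100, seed=7,
            outer_folds=4, inner_folds=3, c_grid=(1.0,),
        )
        assert 1 / 101 <= res["p"] <= 1.0
        assert res["p"] <= 0.05  # strong synthetic signal
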