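"""Efficacy prediction: feature assembly, RFECV selection, nested-CV linear SVM.

The feature panel combines a clinical block (continuous variables plus
one-hot-coded categoricals, 20 columns under the drop-first encoding
documented in ``CLINICAL_ENCODING``), the alpha-band nodal efficiency of
the 10 parieto-occipital ROI electrodes, and the theta-band ROI-mean HHSE —
31 features in the default configuration.

Min-max normalization is fit inside each outer-training split by default
(leakage-safe); a compatibility flag reproduces cohort-wide normalization.
The classifier is a linear-kernel SVM tuned over a logarithmic cost grid by
a 5-fold inner loop inside a stratified 10-fold outer loop; pooled
out-of-fold predictions yield the confusion matrix, accuracy, precision,
specificity and ROC AUC. Significance comes from a label-permutation test
run over the entire pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.feature_selection import RFE, RFECV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .synthetic import R50

DEFAULT_C_GRID = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)

#: Drop-first one-hot map yielding exactly 20 clinical columns:
#: 7 continuous + 2 binary + 3 multi-label seizure flags + 3 etiology +
#: 3 syndrome + 2 MRI dummies.
CLINICAL_ENCODING = {
    "continuous": [
        "seizure_frequency", "bmi", "age_onset", "duration_epilepsy",
        "age_implantation", "n_asms_baseline", "n_asms_historical",
    ],
    "binary": {"prior_surgery": None, "gender": "male"},
    "multilabel": ["seizure_generalized", "seizure_focal", "seizure_unknown"],
    "categorical": {  # column -> dropped reference level
        "etiology": "structural",
        "syndrome": "unclassified",
        "mri": "negative",
    },
}


@dataclass
class FeatureTable:
    """Subjects x features matrix with labels and assembly diagnostics."""

    X: pd.DataFrame
    labels: pd.Series          # values in {"R50", "NR50"}
    dropped: list[str] = field(default_factory=list)
    max_abs_correlation: float | None = None

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def y(self) -> np.ndarray:
        """Binary target: 1 = responder (R50)."""
        return (self.labels == R50).to_numpy(dtype=int)

    def normalized(self) -> "FeatureTable":
        """Cohort-wide min-max normalization of every feature to [0, 1]."""
        lo, hi = self.X.min(), self.X.max()
        return FeatureTable(
            X=(self.X - lo) / (hi - lo),
            labels=self.labels,
            dropped=list(self.dropped),
            max_abs_correlation=self.max_abs_correlation,
        )


def encode_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """One-hot-code the clinical table into its 20-column numeric block."""
    enc = CLINICAL_ENCODING
    out = clinical[enc["continuous"]].astype(float).copy()
    out["prior_surgery"] = clinical["prior_surgery"].astype(int)
    out["gender_male"] = (clinical["gender"] == enc["binary"]["gender"]).astype(int)
    for col in enc["multilabel"]:
        out[col] = clinical[col].astype(int)
    for col, reference in enc["categorical"].items():
        dummies = pd.get_dummies(clinical[col], prefix=col).astype(int)
        ref_col = f"{col}_{reference}"
        keep = [c for c in dummies.columns if c != ref_col]
        # absent levels encode as all-zero columns so the width is stable
        vocab = {
            "etiology": ("structural", "immune", "genetic", "unknown"),
            "syndrome": ("IS", "LGS", "EOEE", "unclassified"),
            "mri": ("multifocal", "focal", "negative"),
        }[col]
        for level in vocab:
            name = f"{col}_{level}"
            if level == reference:
                continue
            out[name] = dummies[name] if name in keep else 0
    return out


def assemble_features(
    clinical: pd.DataFrame,
    alpha_nodal_efficiency: pd.DataFrame,
    theta_roi_hhse: pd.Series,
    normalize: bool = False,
) -> FeatureTable:
    """Build the multi-modal feature matrix.

    ``alpha_nodal_efficiency`` holds one column per parieto-occipital ROI
    electrode; ``theta_roi_hhse`` is the theta-band ROI-mean entropy. All
    three sources must cover the same subjects. Zero-range (constant)
    features are dropped with a warning. With ``normalize=True`` the matrix
    is min-max scaled cohort-wide (the literal, leakage-prone variant);
    leave it False to let the cross-validation scale inside training folds.
    """
    clinical_idx = set(clinical.index)
    for name, idx in (
        ("network metrics", set(alpha_nodal_efficiency.index)),
        ("HHSE", set(theta_roi_hhse.index)),
    ):
        missing = sorted(clinical_idx - idx) + sorted(idx - clinical_idx)
        if missing:
            raise ValueError(f"subject mismatch between clinical table and {name}: {missing}")

    label_col = clinical["label"] if "label" in clinical else None
    clin = clinical.drop(columns=[c for c in ("label",) if c in clinical])
    blocks = [
        encode_clinical(clin),
        alpha_nodal_efficiency.reindex(clin.index).add_prefix("alpha_ne_"),
        theta_roi_hhse.reindex(clin.index).rename("theta_roi_hhse").to_frame(),
    ]
    X = pd.concat(blocks, axis=1).astype(float)

    ranges = X.max() - X.min()
    dropped = list(X.columns[ranges == 0])
    if dropped:
        warnings.warn(f"dropping zero-range feature(s): {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)

    corr = X.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    ft = FeatureTable(
        X=X,
        labels=label_col if label_col is not None else pd.Series(index=X.index, dtype=object),
        dropped=dropped,
        max_abs_correlation=float(np.nanmax(corr)) if corr.size else None,
    )
    return ft.normalized() if normalize else ft


def _svm(C: float = 1.0) -> SVC:
    return SVC(kernel="linear", C=C)


def rfecv_select(
    ft: FeatureTable,
    cv_folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
    scoring: str = "accuracy",
) -> dict:
    """Recursive feature elimination with cross-validated cardinality choice.

    Features are removed one at a time by smallest absolute SVM weight; the
    returned set is the cardinality with the highest mean CV score (ties go
    to the smaller cardinality). Deterministic given ``seed``.
    """
    X = ft.X
    if not all(np.issubdtype(dt, np.number) for dt in X.dtypes):
        raise ValueError("all features must be numeric")
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    selector = RFECV(
        estimator=_svm(C), step=1, cv=cv, scoring=scoring, min_features_to_select=1
    )
    Xs = MinMaxScaler().fit_transform(X.to_numpy())
    selector.fit(Xs, ft.y)
    curve = np.asarray(selector.cv_results_["mean_test_score"], dtype=float)
    # smallest cardinality whose mean CV score ties the maximum
    n_best = int(np.flatnonzero(curve >= curve.max() - 1e-12)[0]) + 1
    support = selector.support_
    if n_best != int(selector.n_features_):
        refit = RFE(estimator=_svm(C), n_features_to_select=n_best, step=1)
        refit.fit(Xs, ft.y)
        support = refit.support_
    return {
        "selected": [n for n, keep in zip(X.columns, support) if keep],
        "n_selected": n_best,
        "score_curve": curve,
        "cardinalities": np.arange(1, len(curve) + 1),
    }


@dataclass
class CvReport:
    """Nested cross-validation performance summary."""

    accuracy: float
    precision: float
    specificity: float
    sensitivity: float
    auc: float
    confusion: np.ndarray          # rows true [NR50, R50], cols predicted
    fold_accuracies: list[float]
    mean_fold_accuracy: float
    best_c_per_fold: list[float]
    selected_per_fold: list[list[str]] | None
    weight_ranges: dict            # feature -> [min, max] over folds
    roc: dict                      # fpr, tpr arrays (pooled scores)
    permutation_p: float | None = None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "auc": self.auc,
            "confusion": self.confusion.tolist(),
            "fold_accuracies": self.fold_accuracies,
            "mean_fold_accuracy": self.mean_fold_accuracy,
            "best_c_per_fold": self.best_c_per_fold,
            "selected_per_fold": self.selected_per_fold,
            "weight_ranges": self.weight_ranges,
            "roc": {k: list(map(float, v)) for k, v in self.roc.items()},
            "permutation_p": self.permutation_p,
            "config": self.config,
        }


def _make_pipeline(global_normalization: bool) -> Pipeline:
    steps = [] if global_normalization else [("scale", MinMaxScaler())]
    steps.append(("svm", _svm()))
    return Pipeline(steps)


def nested_cv_svm(
    ft: FeatureTable,
    inner_folds: int = 5,
    outer_folds: int = 10,
    c_grid=DEFAULT_C_GRID,
    seed: int = 0,
    select: bool = False,
    global_normalization: bool = False,
    pipeline_factory=None,
) -> CvReport:
    """Nested cross-validation of the linear SVM.

    The inner loop grid-searches the cost parameter on the outer-training
    portion only; the held-out fold is predicted once. With ``select=True``
    an RFECV runs inside each outer-training split before the grid search.
    ``pipeline_factory`` (mainly for leakage tests) supplies the estimator
    pipeline; it must expose ``svm`` as its final step.
    """
    X_full = ft.X.to_numpy(dtype=float)
    y = ft.y
    names = ft.feature_names
    if global_normalization:
        lo, hi = X_full.min(axis=0), X_full.max(axis=0)
        X_full = (X_full - lo) / np.where(hi > lo, hi - lo, 1.0)

    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed + 1)

    y_pred = np.empty_like(y)
    scores = np.empty(len(y), dtype=float)
    fold_acc, best_cs = [], []
    selected_per_fold = [] if select else None
    weight_lo = {n: np.inf for n in names}
    weight_hi = {n: -np.inf for n in names}

    for train_idx, test_idx in outer.split(X_full, y):
        X_tr, y_tr = X_full[train_idx], y[train_idx]
        X_te = X_full[test_idx]
        if np.unique(y_tr).size < 2:
            raise ValueError("a class is absent from an outer-training split")
        fold_names = names
        if select:
            sub = FeatureTable(
                X=pd.DataFrame(X_tr, columns=names),
                labels=pd.Series(np.where(y_tr == 1, "R50", "NR50")),
            )
            sel = rfecv_select(sub, cv_folds=inner_folds, seed=seed)
            fold_names = sel["selected"]
            selected_per_fold.append(fold_names)
            cols = [names.index(n) for n in fold_names]
            X_tr, X_te = X_tr[:, cols], X_te[:, cols]
        pipe = pipeline_factory() if pipeline_factory else _make_pipeline(global_normalization)
        grid = GridSearchCV(
            pipe, {"svm__C": list(c_grid)}, cv=inner, scoring="accuracy", refit=True
        )
        grid.fit(X_tr, y_tr)
        best_cs.append(float(grid.best_params_["svm__C"]))
        y_hat = grid.predict(X_te)
        y_pred[test_idx] = y_hat
        scores[test_idx] = grid.decision_function(X_te)
        fold_acc.append(float((y_hat == y[test_idx]).mean()))
        coef = grid.best_estimator_.named_steps["svm"].coef_.ravel()
        for n, w in zip(fold_names, coef):
            weight_lo[n] = min(weight_lo[n], float(w))
            weight_hi[n] = max(weight_hi[n], float(w))

    tp = int(((y_pred == 1) & (y == 1)).sum())
    tn = int(((y_pred == 0) & (y == 0)).sum())
    fp = int(((y_pred == 1) & (y == 0)).sum())
    fn = int(((y_pred == 0) & (y == 1)).sum())
    confusion = np.array([[tn, fp], [fn, tp]])
    auc = float(roc_auc_score(y, scores))
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(y, scores)
    weight_ranges = {
        n: [weight_lo[n], weight_hi[n]] for n in names if np.isfinite(weight_lo[n])
    }
    return CvReport(
        accuracy=(tp + tn) / len(y),
        precision=tp / (tp + fp) if (tp + fp) else float("nan"),
        specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
        sensitivity=tp / (tp + fn) if (tp + fn) else float("nan"),
        auc=auc,
        confusion=confusion,
        fold_accuracies=fold_acc,
        mean_fold_accuracy=float(np.mean(fold_acc)),
        best_c_per_fold=best_cs,
        selected_per_fold=selected_per_fold,
        weight_ranges=weight_ranges,
        roc={"fpr": fpr, "tpr": tpr},
        config={
            "inner_folds": inner_folds,
            "outer_folds": outer_folds,
            "c_grid": list(c_grid),
            "seed": seed,
            "select": select,
            "global_normalization": global_normalization,
        },
    )


def permutation_test(
    ft: FeatureTable,
    n_permutations: int = 100,
    seed: int = 0,
    observed: CvReport | None = None,
    **cv_kwargs,
) -> dict:
    """Label-permutation significance of the nested-CV accuracy.

    Labels are shuffled before the *entire* pipeline (selection included),
    so the null respects every data-dependent step.
    p = (1 + #{permuted accuracy >= observed}) / (1 + n_permutations).
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if observed is None:
        observed = nested_cv_svm(ft, **cv_kwargs)
    rng = np.random.default_rng(seed)
    count = 0
    null_acc = []
    labels = ft.labels.to_numpy()
    for _ in range(n_permutations):
        perm = rng.permutation(len(labels))
        ft_perm = FeatureTable(
            X=ft.X, labels=pd.Series(labels[perm], index=ft.labels.index)
        )
        rep = nested_cv_svm(ft_perm, **cv_kwargs)
        null_acc.append(rep.accuracy)
        if rep.accuracy >= observed.accuracy:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return {"p": p, "observed_accuracy": observed.accuracy, "null_accuracies": null_acc}
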