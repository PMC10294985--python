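"""RBF-SVM epoch classification and patient-independent evaluation.

The classifier is an RBF-kernel support vector machine on z-scored
features (scaling fitted on training folds only — the 15 features mix
seconds, g² and breaths/min).  Evaluation is leave-one-patient-out: all
epochs of the test patient are excluded from training; when the test
patient has several seizure events, a double leave-one-seizure-out inner
loop holds out one event (its seizure epoch plus the non-seizure epochs
anchored to it) while the patient's remaining events join the training
set.  Performance is summarised as SEN, SPE, ACC, precision, F1, the
false-alarm rate per monitored hour (FAH) and the ROC AUC of the SVM
decision scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, validate_data

from .epoching import EPOCH_S, SEIZURE
from .features import FEATURE_NAMES, MODE_FEATURES


class SeizureClassifier(ClassifierMixin, BaseEstimator):
    """Z-scoring RBF-SVM for seizure / non-seizure epochs.

    Parameters
    ----------
    C : float
        SVM regularisation strength.
    gamma : float or {"scale", "auto"}
        RBF kernel width (sklearn convention).
    standardize : bool
        Z-score features with training-fold statistics before the SVM.
    class_weight : None or "balanced"
        Optional reweighting; the default keeps the plain SVM, which
        handles the ~1:9 epoch imbalance adequately.
    random_state : int
        Seed for the underlying SVC (tie-breaking reproducibility).
    """

    def __init__(
        self,
        C: float = 1.0,
        gamma="scale",
        standardize: bool = True,
        class_weight=None,
        random_state: int = 0,
    ):
        self.C = C
        self.gamma = gamma
        self.standardize = standardize
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training set contains a single class; need both")
        steps = []
        if self.standardize:
            steps.append(("scale", StandardScaler()))
        steps.append(
            (
                "svm",
                SVC(
                    kernel="rbf",
                    C=self.C,
                    gamma=self.gamma,
                    class_weight=self.class_weight,
                    random_state=self.random_state,
                ),
            )
        )
        self.pipeline_ = Pipeline(steps).fit(X, y)
        self.classes_ = self.pipeline_.named_steps["svm"].classes_
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.pipeline_.predict(X)

    def decision_function(self, X):
        """Signed distance to the separating surface (positive class score)."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.pipeline_.decision_function(X)


# ---------------------------------------------------------------------------
# cross-validation


def _fit_predict(train: pd.DataFrame, test: pd.DataFrame, feature_cols, cfg) -> pd.DataFrame:
    clf = SeizureClassifier(**cfg)
    y_train = (train["label"] == SEIZURE).astype(int).to_numpy()
    clf.fit(train[list(feature_cols)].to_numpy(), y_train)
    Xt = test[list(feature_cols)].to_numpy()
    out = test[["subject_id", "epoch_start_s", "seizure_group_id", "label"]].copy()
    out["y_true"] = (test["label"] == SEIZURE).astype(int).to_numpy()
    out["y_pred"] = clf.predict(Xt)
    out["score"] = clf.decision_function(Xt)
    return out


def run_cross_validation(
    dataset: pd.DataFrame,
    feature_cols=FEATURE_NAMES,
    **cfg,
) -> pd.DataFrame:
    """Leave-one-patient-out CV with a leave-one-seizure-out inner loop.

    ``dataset`` is the feature matrix from :func:`features.extract_features`
    (columns ``subject_id``, ``seizure_group_id``, ``label`` plus features).
    Every epoch receives exactly one out-of-fold prediction; no training
    fold ever contains the test epoch's subject, nor — in the inner loop —
    its seizure group.  Returns the prediction table with ``y_true``,
    ``y_pred`` (1 = seizure) and the SVM decision ``score``.
    """
    subjects = dataset["subject_id"].unique()
    if len(subjects) < 2:
        raise ValueError("need ≥ 2 subjects for leave-one-patient-out CV")
    missing = [c for c in feature_cols if c not in dataset.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    preds = []
    for subj in subjects:
        is_test_subj = dataset["subject_id"] == subj
        others = dataset[~is_test_subj]
        subj_df = dataset[is_test_subj]
        groups = subj_df["seizure_group_id"].unique()
        if len(groups) > 1:
            for g in groups:
                in_group = subj_df["seizure_group_id"] == g
                train = pd.concat([others, subj_df[~in_group]], ignore_index=True)
                preds.append(_fit_predict(train, subj_df[in_group], feature_cols, cfg))
        else:
            preds.append(_fit_predict(others, subj_df, feature_cols, cfg))
    return pd.concat(preds, ignore_index=True)


# ---------------------------------------------------------------------------
# metrics


@dataclass
class EvaluationCounts:
    """Confusion counts over out-of-fold epoch predictions."""

    tp: int
    fp: int
    tn: int
    fn: int
    monitored_hours: float

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class MetricsReport:
    sen: float
    spe: float
    acc: float
    precision: float
    recall: float
    f1: float
    fah: float
    auc: float = float("nan")
    roc: list = field(default_factory=list)
    undefined: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dict(
            sen=self.sen, spe=self.spe, acc=self.acc, precision=self.precision,
            recall=self.recall, f1=self.f1, fah=self.fah, auc=self.auc,
            undefined=list(self.undefined),
        )


def confusion_counts(predictions: pd.DataFrame) -> EvaluationCounts:
    """TP/FP/TN/FN and the monitored hours (epochs × 5 min) they cover."""
    y, p = predictions["y_true"].to_numpy(), predictions["y_pred"].to_numpy()
    return EvaluationCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        fp=int(np.sum((y == 0) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fn=int(np.sum((y == 1) & (p == 0))),
        monitored_hours=len(predictions) * EPOCH_S / 3600.0,
    )


def _ratio(num: float, den: float, name: str, undefined: list) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def compute_metrics(counts: EvaluationCounts) -> MetricsReport:
    """SEN, SPE, ACC, precision/recall/F1 and false alarms per hour.

    Zero-denominator metrics are reported as 0 and listed in
    ``report.undefined`` rather than raising.
    """
    undef: list = []
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sen = _ratio(tp, tp + fn, "sen", undef)
    spe = _ratio(tn, tn + fp, "spe", undef)
    acc = _ratio(tp + tn, tp + tn + fp + fn, "acc", undef)
    precision = _ratio(tp, tp + fp, "precision", undef)
    recall = sen
    f1 = _ratio(2 * precision * recall, precision + recall, "f1", undef)
    fah = _ratio(fp, counts.monitored_hours, "fah", undef)
    return MetricsReport(sen, spe, acc, precision, recall, f1, fah, undefined=undef)


def compute_roc_auc(scores, truth) -> tuple[list, float]:
    """ROC points and trapezoidal AUC from decision scores.

    Equivalent to the Mann–Whitney concordant-pair statistic; ties count
    half.  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if len(np.unique(truth)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(truth, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def evaluate_predictions(predictions: pd.DataFrame) -> MetricsReport:
    """Full metrics report (including ROC/AUC) for an out-of-fold table."""
    report = compute_metrics(confusion_counts(predictions))
    y = predictions["y_true"].to_numpy()
    if len(np.unique(y)) == 2:
        report.roc, report.auc = compute_roc_auc(predictions["score"].to_numpy(), y)
    return report


def run_ablation(dataset: pd.DataFrame, mode: str = "full", **cfg) -> MetricsReport:
    """Cross-validate one detector mode.

    ``full`` uses all 15 features, ``ecg_only`` the 10 HRV features and
    ``resp_acc`` the 4 movement + 1 respiration features.
    """
    if mode not in MODE_FEATURES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {sorted(MODE_FEATURES)}")
    preds = run_cross_validation(dataset, feature_cols=MODE_FEATURES[mode], **cfg)
    return evaluate_predictions(preds)
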