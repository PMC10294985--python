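import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neoseize.features import FEATURE_NAMES, MODE_FEATURES
from neoseize.model import (
    EvaluationCounts,
    SeizureClassifier,
    compute_metrics,
    compute_roc_auc,
    confusion_counts,
    evaluate_predictions,
    run_ablation,
    run_cross_validation,
)


def _toy_dataset(n_subjects=4, groups_per_subject=2, seed=0, separation=3.0):
    """Feature table with a planted class separation on every feature."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for g in range(groups_per_subject):
            for label, n in (("seizure", 1), ("non_seizure", 9)):
                for k in range(n):
                    base = separation if label == "seizure" else 0.0
                    feats = {f: base + rng.normal() for f in FEATURE_NAMES}
                    rows.append(
                        dict(
                            subject_id=f"S{s}",
                            epoch_start_s=float(len(rows)) * 300.0,
                            seizure_group_id=g,
                            label=label,
                            **feats,
                        )
                    )
    return pd.DataFrame(rows)


class TestSeizureClassifier:
    def test_separable_clusters_learned_perfectly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (10, 2)), rng.normal(5, 0.3, (10, 2))])
        y = np.array([0] * 10 + [1] * 10)
        clf = SeizureClassifier().fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_xor_pattern_needs_and_gets_nonlinearity(self):
        rng = np.random.default_rng(1)
        centers = [(0, 0, 0), (0, 3, 1), (3, 0, 1), (3, 3, 0)]
        X = np.vstack([rng.normal(c[:2], 0.2, (15, 2)) for c in centers])
        y = np.repeat([c[2] for c in centers], 15)
        clf = SeizureClassifier(C=10.0).fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] + 0.3 * rng.normal(size=40) > 0).astype(int)
        p1 = SeizureClassifier(random_state=5).fit(X, y).predict(X)
        p2 = SeizureClassifier(random_state=5).fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_training_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="single class"):
            SeizureClassifier().fit(X, np.zeros(5))

    def test_feature_count_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 4))
        y = np.array([0, 1] * 10)
        clf = SeizureClassifier().fit(X, y)
        with pytest.raises(ValueError):
            clf.predict(rng.normal(size=(5, 3)))

    def test_sklearn_param_interface(self):
        clf = SeizureClassifier(C=2.0)
        assert clf.get_params()["C"] == 2.0
        clf.set_params(C=0.5)
        assert clf.C == 0.5


class TestCrossValidation:
    def test_every_epoch_predicted_exactly_once(self):
        df = _toy_dataset()
        preds = run_cross_validation(df)
        assert len(preds) == len(df)
        key = preds[["subject_id", "epoch_start_s"]].apply(tuple, axis=1)
        assert key.is_unique

    def test_single_subject_rejected(self):
        df = _toy_dataset(n_subjects=1)
        with pytest.raises(ValueError, match="2 subjects"):
            run_cross_validation(df)

    def test_no_leakage_audit(self):
        """No training fold may contain the test epoch's subject, nor the
        test seizure group within the inner leave-one-seizure-out loop."""
        df = _toy_dataset(n_subjects=3, groups_per_subject=3)
        audit: list = []

        import neoseize.model as model

        original = model._fit_predict

        def spy(train, test, feature_cols, cfg):
            audit.append(
                (
                    set(zip(train["subject_id"], train["seizure_group_id"])),
                    set(zip(test["subject_id"], test["seizure_group_id"])),
                )
            )
            return original(train, test, feature_cols, cfg)

        model._fit_predict, model.__dict__["_fit_predict"] = spy, spy
        try:
            run_cross_validation(df)
        finally:
            model._fit_predict = original
        assert len(audit) == 9  # 3 subjects × 3 inner folds
        for train_ids, test_ids in audit:
            assert not (train_ids & test_ids)
            test_subjects = {s for s, _ in test_ids}
            assert len(test_subjects) == 1

    def test_subject_without_multiple_groups_uses_outer_fold_only(self):
        df = _toy_dataset(n_subjects=2, groups_per_subject=1)
        preds = run_cross_validation(df)
        assert len(preds) == len(df)


class TestMetrics:
    def test_hand_computed_confusion_example(self):
        counts = EvaluationCounts(tp=4, fn=6, tn=27, fp=1, monitored_hours=2.0)
        r = compute_metrics(counts)
        assert r.sen == pytest.approx(0.4)
        assert r.spe == pytest.approx(27 / 28)
        assert r.acc == pytest.approx(31 / 38)
        assert r.precision == pytest.approx(0.8)
        assert r.f1 == pytest.approx(2 * 0.8 * 0.4 / 1.2)
        assert r.fah == pytest.approx(0.5)

    def test_counts_from_predictions(self):
        preds = pd.DataFrame(
            dict(y_true=[1, 0, 0, 0, 1], y_pred=[1, 1, 0, 0, 0])
        )
        c = confusion_counts(preds)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 2, 1)
        assert c.monitored_hours == pytest.approx(5 * 300 / 3600)

    def test_no_false_positives_means_zero_fah(self):
        c = EvaluationCounts(tp=1, fp=0, tn=9, fn=0, monitored_hours=5.0)
        assert compute_metrics(c).fah == 0.0

    def test_undefined_precision_flagged_not_raised(self):
        c = EvaluationCounts(tp=0, fp=0, tn=5, fn=2, monitored_hours=1.0)
        r = compute_metrics(c)
        assert r.precision == 0.0 and r.f1 == 0.0
        assert "precision" in r.undefined

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        tn=st.integers(0, 50), fn=st.integers(0, 50),
    )
    def test_metric_arithmetic_property(self, tp, fp, tn, fn):
        c = EvaluationCounts(tp=tp, fp=fp, tn=tn, fn=fn,
                             monitored_hours=(tp + fp + tn + fn) / 12 or 1.0)
        r = compute_metrics(c)
        if tp + fn:
            assert r.sen == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert r.spe == pytest.approx(tn / (tn + fp))
        assert r.recall == r.sen
        assert 0 <= r.f1 <= 1


class TestROCAUC:
    def test_perfect_separation(self):
        _, auc = compute_roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_scores_equal_gives_half(self):
        _, auc = compute_roc_auc([0.5] * 8, [1, 0] * 4)
        assert auc == pytest.approx(0.5)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        scores=st.lists(st.floats(-3, 3), min_size=4, max_size=60),
        data=st.data(),
    )
    def test_auc_matches_pairwise_oracle(self, scores, data):
        """Trapezoidal AUC equals the exhaustive concordant-pair statistic."""
        y = data.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        y = np.array(y)
        if len(np.unique(y)) < 2:
            y[0], y[-1] = 0, 1
        scores = np.array(scores)
        _, auc = compute_roc_auc(scores, y)
        pos, neg = scores[y == 1], scores[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-9)

    def test_monotone_transform_leaves_auc_unchanged(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=30)
        y = (s + rng.normal(0, 1, 30) > 0).astype(int)
        _, a1 = compute_roc_auc(s, y)
        _, a2 = compute_roc_auc(np.exp(2 * s), y)
        assert a1 == pytest.approx(a2)


class TestAblation:
    @pytest.mark.parametrize("mode,width", [("full", 15), ("ecg_only", 10), ("resp_acc", 5)])
    def test_mode_feature_widths(self, mode, width):
        assert len(MODE_FEATURES[mode]) == width

    def test_ablation_runs_each_mode(self):
        df = _toy_dataset()
        r = run_ablation(df, mode="ecg_only")
        assert 0 <= r.auc <= 1

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown mode"):
            run_ablation(_toy_dataset(), mode="eeg")


def test_evaluate_predictions_bundles_roc():
    df = _toy_dataset()
    preds = run_cross_validation(df)
    r = evaluate_predictions(preds)
    assert len(r.roc) >= 2
    assert 0 <= r.auc <= 1
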