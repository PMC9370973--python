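import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score, matthews_corrcoef

from ppgqc import classify as cl
from ppgqc.exceptions import IntegrityError, ParameterError, TaskError


class TestSplitSubjectwise:
    def test_31_subjects_split_22_9(self):
        train, test = cl.split_subjectwise([f"S{i}" for i in range(31)], seed=0)
        assert (len(train), len(test)) == (22, 9)

    def test_round_half_up(self):
        train, test = cl.split_subjectwise([f"S{i}" for i in range(10)], seed=0)
        assert (len(train), len(test)) == (7, 3)

    def test_deterministic_and_disjoint(self):
        subjects = [f"S{i}" for i in range(13)]
        a = cl.split_subjectwise(subjects, seed=3)
        b = cl.split_subjectwise(subjects, seed=3)
        assert a == b
        assert set(a[0]).isdisjoint(a[1])
        assert sorted(a[0] + a[1]) == sorted(subjects)

    def test_too_few_subjects(self):
        with pytest.raises(ParameterError):
            cl.split_subjectwise(["only"], seed=0)


class TestMetricsReport:
    def test_hand_confusion_matrix(self):
        rep = cl.metrics_from_confusion(tp=50, fn=50, tn=90, fp=10)
        assert rep.sens == pytest.approx(0.500)
        assert rep.spec == pytest.approx(0.900)
        assert rep.prec == pytest.approx(0.8333, abs=1e-4)
        assert rep.acc == pytest.approx(0.700)

    def test_mcc_kappa_against_sklearn(self):
        """MCC and Cohen's kappa from the count formulas agree with sklearn
        on the reconstructed label vectors."""
        tp, fp, tn, fn = 50, 10, 90, 50
        y = np.r_[np.ones(tp + fn), np.zeros(tn + fp)]
        pred = np.r_[np.ones(tp), np.zeros(fn), np.zeros(tn), np.ones(fp)]
        rep = cl.metrics_from_confusion(tp=tp, fp=fp, tn=tn, fn=fn)
        assert rep.mcc == pytest.approx(matthews_corrcoef(y, pred), abs=1e-12)
        assert rep.kappa == pytest.approx(cohen_kappa_score(y, pred), abs=1e-12)

    def test_internal_consistency(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            tp, fp, tn, fn = rng.integers(1, 100, 4)
            rep = cl.metrics_from_confusion(int(tp), int(fp), int(tn), int(fn))
            total = tp + fp + tn + fn
            assert rep.acc == pytest.approx((tp + tn) / total, abs=1e-9)
            assert rep.f1 == pytest.approx(
                2 * rep.prec * rep.sens / (rep.prec + rep.sens), abs=1e-9
            )


class _ScoreModel:
    def __init__(self, scores, preds):
        self.scores = np.asarray(scores)
        self.preds = np.asarray(preds)

    def predict(self, X):
        return self.preds

    def decision_scores(self, X):
        return self.scores


class TestEvaluate:
    def test_perfect_scores(self):
        y = np.array([0, 0, 1, 1])
        model = _ScoreModel([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        rep = cl.evaluate(model, np.zeros((4, 1)), y)
        assert (rep.auc, rep.mcc, rep.kappa) == pytest.approx((1.0, 1.0, 1.0))

    def test_constant_scores_auc_half(self):
        y = np.array([0, 1, 0, 1])
        model = _ScoreModel([0.5] * 4, [1, 1, 1, 1])
        assert cl.evaluate(model, np.zeros((4, 1)), y).auc == pytest.approx(0.5)

    def test_single_class_auc_undefined(self):
        y = np.ones(4, dtype=int)
        model = _ScoreModel([0.1, 0.2, 0.3, 0.4], [1, 1, 0, 1])
        rep = cl.evaluate(model, np.zeros((4, 1)), y)
        assert np.isnan(rep.auc)
        assert rep.sens == pytest.approx(0.75)


class TestTaskSpecs:
    def test_task_definitions(self):
        assert cl.TASKS["BQ"].positive == {"F", "E"}
        assert cl.TASKS["HQ1"].negative == {"B", "F"}
        assert cl.TASKS["HQ2"].positive == {"E"}
        assert cl.TASKS["HQ2"].negative == {"F"}

    def test_hq2_rejects_bad_pulses(self):
        with pytest.raises(TaskError):
            cl.TASKS["HQ2"].binarize(np.array(["B", "F", "E"]))


def _separable(n=200, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = np.column_stack([3.0 * y + 0.1 * rng.standard_normal(n),
                         rng.standard_normal(n)])
    labels = np.where(y == 1, "E", "B")
    return pd.DataFrame(X, columns=["a", "b"]), labels, y


class TestTrainModel:
    def test_separable_svm_low_cv_loss(self):
        X, labels, _ = _separable()
        model = cl.train_model("HQ1", "svm", X, labels, cv_folds=5, opt_iters=8, seed=0)
        assert model.cv_loss_ <= 0.02

    def test_permuted_labels_near_majority(self):
        X, labels, y = _separable(seed=1)
        rng = np.random.default_rng(2)
        perm = rng.permutation(labels)
        model = cl.train_model("HQ1", "tree", X, perm, cv_folds=4, opt_iters=4, seed=0)
        rep = cl.evaluate(model, X, cl.TASKS["HQ1"].binarize(perm))
        majority = max(np.mean(perm == "E"), 1 - np.mean(perm == "E"))
        assert rep.acc <= majority + 0.25  # trees can memorize the train set

    def test_single_optimizer_iteration_is_valid(self):
        X, labels, y = _separable(seed=3)
        model = cl.train_model("HQ1", "knn", X, labels, cv_folds=3, opt_iters=1, seed=0)
        assert model.predict(X).shape == (len(X),)

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(TaskError):
            cl.train_model("BQ", "tree", X, np.array(["B", "B", "B"]), opt_iters=1)

    def test_feature_mismatch_detected(self):
        X, labels, _ = _separable(seed=4)
        model = cl.train_model("HQ1", "knn", X, labels, cv_folds=3, opt_iters=1, seed=0)
        with pytest.raises(IntegrityError):
            model.predict(X.rename(columns={"a": "z"}))

    @pytest.mark.parametrize("family", ["naive_bayes", "ensemble", "neural_net"])
    def test_remaining_families_train(self, family):
        X, labels, y = _separable(seed=5, n=120)
        model = cl.train_model("HQ1", family, X, labels, cv_folds=3, opt_iters=2, seed=0)
        rep = cl.evaluate(model, X, y)
        assert rep.acc > 0.8


class _ConstantModel:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


class TestCascade:
    def test_bq_negative_short_circuits_to_b(self):
        cascade = cl.CascadeQualityClassifier(_ConstantModel(0), _ConstantModel(1))
        out = cascade.predict(np.zeros((5, 2)))
        assert (out == "B").all()

    def test_all_positive_gives_e(self):
        cascade = cl.CascadeQualityClassifier(_ConstantModel(1), _ConstantModel(1))
        assert (cascade.predict(np.zeros((4, 2))) == "E").all()

    def test_mixed_stage_outputs(self):
        class Alternating:
            def predict(self, X):
                return np.arange(len(X)) % 2

        cascade = cl.CascadeQualityClassifier(Alternating(), _ConstantModel(1))
        out = cascade.predict(np.zeros((6, 2)))
        assert list(out) == ["B", "E", "B", "E", "B", "E"]
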