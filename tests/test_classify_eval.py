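"""Classifier training, cross-validation bookkeeping, and metrics."""

import numpy as np
import pandas as pd
import pytest

import pocketmotion as pm
from pocketmotion.classify_eval import (
    ClassifierSpec,
    NaiveBayesModel,
    TreeModel,
    cross_validate,
    rmse,
    train,
)


def _separable_toy(n=60, seed=0):
    """Two well-separated Gaussian blobs in 2-D."""
    rng = np.random.default_rng(seed)
    a = rng.normal([0, 0], 0.2, size=(n // 2, 2))
    b = rng.normal([5, 5], 0.2, size=(n // 2, 2))
    df = pd.DataFrame(np.vstack([a, b]), columns=["f1", "f2"])
    df["label"] = ["low"] * (n // 2) + ["high"] * (n // 2)
    return df


class TestTrain:
    @pytest.mark.parametrize("kind", ["tree", "naive_bayes", "smo_svm"])
    def test_separable_toy_reaches_perfect_training_accuracy(self, kind):
        df = _separable_toy()
        model = train(ClassifierSpec(kind), df)
        X = df[["f1", "f2"]].to_numpy()
        assert (model.predict(X) == df["label"].to_numpy()).all()

    def test_single_class_rejected(self):
        df = _separable_toy()
        df["label"] = "low"
        with pytest.raises(pm.ValidationError, match="2 classes"):
            train(ClassifierSpec("tree"), df)

    def test_nan_features_rejected(self):
        df = _separable_toy()
        df.iloc[0, 0] = np.nan
        with pytest.raises(pm.ValidationError, match="non-finite"):
            train(ClassifierSpec("naive_bayes"), df)

    def test_min_leaf_objects_prevents_split_below_30(self):
        """29 instances cannot be split when every leaf needs 30 objects."""
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"f1": rng.normal(size=29)})
        df["label"] = ["low"] * 15 + ["high"] * 14
        model = train(ClassifierSpec("tree"), df)
        assert isinstance(model, TreeModel) and model.n_leaves == 1

    def test_unpruned_tree_has_at_least_as_many_leaves(self, default_dataset):
        pruned = train(ClassifierSpec("tree", pruned=True), default_dataset)
        unpruned = train(ClassifierSpec("tree", pruned=False), default_dataset)
        assert pruned.n_leaves <= unpruned.n_leaves

    def test_naive_bayes_density_is_product_of_univariate_gaussians(self):
        """Hand computation of the independence model on a 2-feature toy."""
        df = _separable_toy(n=40, seed=3)
        model = train(ClassifierSpec("naive_bayes"), df)
        assert isinstance(model, NaiveBayesModel)
        x = np.array([0.1, -0.2])
        for ci, _cls in enumerate(model.classes_):
            expected = 0.0
            for j in range(2):
                mu, var = model.theta_[ci, j], model.var_[ci, j]
                expected += -0.5 * np.log(2 * np.pi * var) - 0.5 * (
                    (x[j] - mu) ** 2 / var
                )
            assert model.class_log_density(x)[ci] == pytest.approx(
                expected, rel=1e-12
            )

    def test_naive_bayes_agrees_with_sklearn(self):
        from sklearn.naive_bayes import GaussianNB

        df = _separable_toy(n=80, seed=5)
        X = df[["f1", "f2"]].to_numpy()
        y = df["label"].to_numpy()
        ours = train(ClassifierSpec("naive_bayes"), df)
        ref = GaussianNB(var_smoothing=0.0).fit(X, y)
        assert (ours.predict(X) == ref.predict(X)).all()
        np.testing.assert_allclose(
            ours.predict_proba(X), ref.predict_proba(X), atol=1e-8
        )


class TestRmse:
    def test_perfect_one_hot_predictions_give_zero(self):
        p = np.eye(5)[[0, 3, 2]]
        assert rmse(p, np.array([0, 3, 2])) == 0.0

    def test_uniform_five_class_closed_form(self):
        p = np.full((10, 5), 0.2)
        y = np.zeros(10, dtype=int)
        expected = np.sqrt((0.8**2 + 4 * 0.2**2) / 5)
        assert rmse(p, y) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.4)

    def test_random_fixture_matches_double_loop(self):
        rng = np.random.default_rng(2)
        p = rng.dirichlet(np.ones(5), size=30)
        y = rng.integers(0, 5, size=30)
        total = 0.0
        for i in range(30):
            for c in range(5):
                truth = 1.0 if c == y[i] else 0.0
                total += (p[i, c] - truth) ** 2
        assert rmse(p, y) == pytest.approx(np.sqrt(total / 150), rel=1e-12)

    def test_unnormalized_rows_rejected(self):
        p = np.full((3, 5), 0.3)
        with pytest.raises(pm.ValidationError, match="sum to 1"):
            rmse(p, np.zeros(3, dtype=int))


class TestCrossValidate:
    def test_leave_one_out_on_10_instances(self):
        df = _separable_toy(n=10, seed=1)
        rep = cross_validate(ClassifierSpec("naive_bayes"), df, k=10, seed=0)
        assert rep.confusion.total == 10

    def test_confusion_total_equals_instance_count(self, default_dataset):
        rep = cross_validate(
            ClassifierSpec("naive_bayes"), default_dataset, k=10, seed=17
        )
        assert rep.confusion.total == len(default_dataset)

    def test_accuracy_equals_trace_over_total(self, default_dataset):
        rep = cross_validate(
            ClassifierSpec("tree"), default_dataset, k=10, seed=17
        )
        cm = rep.confusion.counts
        assert rep.accuracy_pct == pytest.approx(
            100.0 * np.trace(cm) / cm.sum(), rel=1e-12
        )

    def test_k_larger_than_n_rejected(self):
        df = _separable_toy(n=6)
        with pytest.raises(pm.ValidationError):
            cross_validate(ClassifierSpec("tree"), df, k=10)

    def test_seeded_determinism(self, default_dataset):
        a = cross_validate(ClassifierSpec("tree"), default_dataset, k=10, seed=5)
        b = cross_validate(ClassifierSpec("tree"), default_dataset, k=10, seed=5)
        assert np.array_equal(a.confusion.counts, b.confusion.counts)
        assert a.rmse == b.rmse and a.accuracy_pct == b.accuracy_pct

    def test_class_order_is_fixed_activity_order(self, default_dataset):
        rep = cross_validate(
            ClassifierSpec("tree"), default_dataset, k=10, seed=17
        )
        assert rep.confusion.classes == pm.ACTIVITY_LABELS


class TestReport:
    def test_files_written_and_consistent(self, default_dataset, tmp_path):
        rep = cross_validate(ClassifierSpec("tree"), default_dataset, k=10, seed=17)
        cm_path, metrics_path = pm.report(rep, tmp_path)
        lines = cm_path.read_text().strip().splitlines()
        assert len(lines) == 6  # header + 5 class rows
        import json

        metrics = json.loads(metrics_path.read_text())
        # accuracy in JSON equals recomputation from the CSV
        counts = np.array(
            [[int(v) for v in l.split(",")[1:]] for l in lines[1:]]
        )
        assert metrics["accuracy_pct"] == pytest.approx(
            100.0 * np.trace(counts) / counts.sum(), rel=1e-12
        )
        assert metrics["n_instances"] == counts.sum()
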