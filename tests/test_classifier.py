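"""The tanh/tanh intake classifier: training, prediction, CV protocols, metrics."""

import numpy as np
import pytest
from sklearn.metrics import f1_score, precision_score, recall_score

from chewmeter import (
    classification_metrics,
    loso_cv,
    predict,
    select_hidden_units,
    train_ann,
)
from chewmeter.classifier import AnnModel

N_FEATURES = 38


def _clusters(n_per_class=100, separation=6.0, seed=0, n_features=N_FEATURES):
    """Two spherical Gaussian clusters `separation` sigmas apart."""
    rng = np.random.default_rng(seed)
    centre = np.zeros(n_features)
    centre[0] = separation / 2
    x_pos = rng.normal(size=(n_per_class, n_features)) + centre
    x_neg = rng.normal(size=(n_per_class, n_features)) - centre
    x = np.vstack([x_pos, x_neg])
    y = np.concatenate([np.ones(n_per_class, int), -np.ones(n_per_class, int)])
    return x, y


class TestTrainAnn:
    def test_separable_clusters_perfect_training_f1(self):
        x, y = _clusters(100)
        model = train_ann(x, y, n_hidden=5, seed=0)
        metrics = classification_metrics(predict(model, x), y)
        assert metrics.f1 == 1.0

    def test_training_is_deterministic(self):
        x, y = _clusters(60, seed=4)
        p1 = predict(train_ann(x, y, seed=7), x)
        p2 = predict(train_ann(x, y, seed=7), x)
        np.testing.assert_array_equal(p1, p2)

    def test_loss_decreases_from_initialisation(self):
        x, y = _clusters(60, seed=2)
        model = train_ann(x, y, seed=0)
        assert model.loss_curve[-1] < model.loss_curve[0]

    def test_single_class_rejected(self):
        x, _ = _clusters(20)
        with pytest.raises(ValueError, match="single class"):
            train_ann(x, np.ones(len(x), int))

    def test_dimension_mismatch_rejected(self):
        x, y = _clusters(20)
        model = train_ann(x, y, seed=0)
        with pytest.raises(ValueError, match="features"):
            predict(model, x[:, :10])

    def test_json_round_trip(self, tmp_path):
        x, y = _clusters(40, seed=1)
        model = train_ann(x, y, seed=3)
        model.to_json(tmp_path / "m.json")
        back = AnnModel.from_json(tmp_path / "m.json")
        np.testing.assert_array_equal(predict(back, x), predict(model, x))


class TestPredict:
    def test_cluster_members_classified(self):
        x, y = _clusters(100, seed=5)
        model = train_ann(x, y, seed=0)
        deep_pos = np.zeros((1, N_FEATURES))
        deep_pos[0, 0] = 5.0
        assert predict(model, deep_pos)[0] == 1
        assert predict(model, -deep_pos)[0] == -1

    def test_empty_input_gives_empty_output(self):
        x, y = _clusters(40)
        model = train_ann(x, y, seed=0)
        assert len(predict(model, np.empty((0, N_FEATURES)))) == 0

    def test_outputs_are_plus_minus_one(self):
        x, y = _clusters(50, seed=6)
        model = train_ann(x, y, seed=0)
        assert set(np.unique(predict(model, x))) <= {-1, 1}


class TestClassificationMetrics:
    def test_worked_example(self):
        pred = [1] * 10 + [-1] * 1 + [1] * 0 + [-1] * 5
        true = [1] * 9 + [-1] * 1 + [1] * 1 + [-1] * 5
        m = classification_metrics(pred, true)
        assert (m.tp, m.fp, m.fn) == (9, 1, 1)
        assert m.precision == pytest.approx(0.9)
        assert m.recall == pytest.approx(0.9)
        assert m.f1 == pytest.approx(0.9)

    def test_perfect_prediction(self):
        m = classification_metrics([1, -1, 1], [1, -1, 1])
        assert m.f1 == 1.0

    def test_degenerate_zero_tp(self):
        m = classification_metrics([-1, -1], [1, 1])
        assert m.f1 == 0.0
        assert m.precision == 0.0
        assert m.recall == 0.0

    def test_matches_sklearn_on_random_pairs(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(2, 30))
            pred = rng.choice([-1, 1], size=n)
            true = rng.choice([-1, 1], size=n)
            m = classification_metrics(pred, true)
            assert m.f1 == pytest.approx(
                f1_score(true, pred, pos_label=1, zero_division=0), abs=1e-12
            )
            assert m.precision == pytest.approx(
                precision_score(true, pred, pos_label=1, zero_division=0), abs=1e-12
            )
            assert m.recall == pytest.approx(
                recall_score(true, pred, pos_label=1, zero_division=0), abs=1e-12
            )

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        pred = rng.choice([-1, 1], size=50)
        true = rng.choice([-1, 1], size=50)
        perm = rng.permutation(50)
        assert (
            classification_metrics(pred, true).f1
            == classification_metrics(pred[perm], true[perm]).f1
        )

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics([0, 1], [1, 1])
        with pytest.raises(ValueError):
            classification_metrics([1], [1, -1])


class TestLosoCv:
    def _dataset(self, n_subjects=4, n_per_class=30, seed=0):
        return {
            f"s{i}": _clusters(n_per_class, seed=seed + i) for i in range(n_subjects)
        }

    def test_separable_subjects_high_f1(self):
        result = loso_cv(self._dataset(6), n_hidden=5, seeds=(0,))
        assert result.mean_f1 >= 0.95

    def test_identical_subjects_get_identical_metrics(self):
        x, y = _clusters(30, seed=9)
        result = loso_cv({"a": (x, y), "b": (x, y)}, seeds=(0,))
        ma, mb = result.per_subject["a"], result.per_subject["b"]
        assert (ma.tp, ma.fp, ma.fn, ma.tn) == (mb.tp, mb.fp, mb.fn, mb.tn)

    def test_permuted_labels_fall_to_chance(self):
        # with labels shuffled independently of the features, held-out F1
        # should sit near the balanced-class chance level of 0.5
        rng = np.random.default_rng(5)
        dataset = {}
        for i in range(5):
            x, y = _clusters(60, seed=i)
            dataset[f"s{i}"] = (x, rng.permutation(y))
        result = loso_cv(dataset, n_hidden=5, seeds=(0,))
        assert abs(result.mean_f1 - 0.5) <= 0.1

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            loso_cv(self._dataset(1))

    def test_empty_subject_rejected(self):
        data = self._dataset(2)
        data["empty"] = (np.empty((0, N_FEATURES)), np.empty(0, int))
        with pytest.raises(ValueError, match="no epochs"):
            loso_cv(data)


class TestSelectHiddenUnits:
    def test_linear_problem_saturates_early(self):
        x, y = _clusters(60, separation=8.0, seed=3)
        chosen, table = select_hidden_units(
            x, y, k_range=(1, 2, 3, 6), n_folds=4, n_reps=2, seed=0
        )
        assert chosen <= 3
        assert set(table) == {1, 2, 3, 6}

    def test_zero_tolerance_is_argmax(self):
        x, y = _clusters(40, seed=1)
        chosen, table = select_hidden_units(
            x, y, k_range=(1, 2), n_folds=3, n_reps=1, seed=0, tolerance=0.0
        )
        best = max(table.values())
        assert chosen == min(k for k, v in table.items() if v == best)

    def test_single_size_forced(self):
        x, y = _clusters(30, seed=2)
        chosen, _ = select_hidden_units(x, y, k_range=(4,), n_folds=3, n_reps=1, seed=0)
        assert chosen == 4

    def test_more_folds_than_examples_rejected(self):
        x, y = _clusters(5)
        with pytest.raises(ValueError):
            select_hidden_units(x, y, k_range=(1,), n_folds=50, n_reps=1)
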