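"""Sequence classifiers: gradients, training protocol, and grouped CV."""

import numpy as np
import pytest

from affmotion import _nn
from affmotion import models as md


def _toy_sequences(n_per_class=30, T=6, F=4, n_classes=3, sep=2.0, seed=0):
    """Separable sequence data: class k oscillates around level k*sep."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for k in range(n_classes):
        base = k * sep
        for _ in range(n_per_class):
            x = base + 0.3 * np.sin(np.arange(T))[:, None] + rng.normal(0, 0.3, (T, F))
            X.append(x)
            y.append(f"c{k}")
    return np.stack(X), np.array(y)


def _numeric_grad(f, param, eps=1e-6, n_checks=6, rng=None):
    rng = rng or np.random.default_rng(0)
    flat = param.ravel()
    idx = rng.choice(flat.size, size=min(n_checks, flat.size), replace=False)
    grads = np.empty(len(idx))
    for k, i in enumerate(idx):
        old = flat[i]
        flat[i] = old + eps
        lp = f()
        flat[i] = old - eps
        lm = f()
        flat[i] = old
        grads[k] = (lp - lm) / (2 * eps)
    return idx, grads


@pytest.mark.parametrize("cell", ["lstm", "rnn"])
def test_recurrent_backprop_matches_finite_differences(cell):
    rng = np.random.default_rng(1)
    X = rng.normal(size=(5, 7, 3))
    mask = np.ones((5, 7), dtype=bool)
    mask[0, 5:] = False  # one padded sequence
    y = rng.integers(0, 3, size=5)
    net = _nn.RecurrentNet(3, (4, 3), 3, rng, cell=cell)

    def loss():
        return _nn.cross_entropy(net.forward(X, mask), y)[0]

    l0, dl = _nn.cross_entropy(net.forward(X, mask), y)
    net.backward(dl)
    for p, g in zip(net.params, net.grads):
        idx, num = _numeric_grad(loss, p, rng=rng)
        np.testing.assert_allclose(g.ravel()[idx], num, rtol=1e-4, atol=1e-7)


def test_conv_and_pool_backprop_match_finite_differences():
    """Conv -> pool -> dense stack without ReLU: the loss is smooth in the
    parameters almost everywhere (pooling ties have measure zero on
    continuous random conv outputs), so central differences apply."""
    rng = np.random.default_rng(2)
    X = rng.normal(size=(4, 9, 6))
    y = rng.integers(0, 2, size=4)
    conv, pool, flat = _nn.Conv3x3(1, 3, rng), _nn.MaxPool2x2(), _nn.Flatten()
    dense = _nn.Dense(3 * 4 * 3, 2, rng)
    layers = [conv, pool, flat, dense]

    def forward():
        h = X[:, None, :, :]
        for l in layers:
            h = l.forward(h)
        return h

    def loss():
        return _nn.cross_entropy(forward(), y)[0]

    _, dl = _nn.cross_entropy(forward(), y)
    d = dl
    for l in reversed(layers):
        d = l.backward(d)
    for p, g in [(conv.W, conv.grads[0]), (conv.b, conv.grads[1]),
                 (dense.W, dense.grads[0]), (dense.b, dense.grads[1])]:
        idx, num = _numeric_grad(loss, p, rng=rng)
        np.testing.assert_allclose(g.ravel()[idx], num, rtol=1e-4, atol=1e-7)


def test_relu_backward_masks_negative_inputs():
    x = np.array([[-1.0, 0.5], [2.0, -3.0]])
    r = _nn.ReLU()
    r.forward(x)
    np.testing.assert_array_equal(r.backward(np.ones_like(x)),
                                  [[0.0, 1.0], [1.0, 0.0]])


def test_padded_steps_do_not_influence_recurrent_output():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(2, 6, 3))
    mask = np.ones((2, 6), dtype=bool)
    mask[:, 4:] = False
    net = _nn.RecurrentNet(3, (5,), 2, rng, cell="lstm")
    out1 = net.forward(X, mask)
    X2 = X.copy()
    X2[:, 4:] = 99.0  # garbage in the padded region
    out2 = net.forward(X2, mask)
    np.testing.assert_allclose(out1, out2, atol=1e-12)


class TestEstimators:
    def test_softmax_probabilities_sum_to_one(self):
        X, y = _toy_sequences(n_per_class=4, n_classes=7)
        est = md.LSTMClassifier(hidden_units=(6,), max_epochs=1, random_state=0)
        est.fit(X, y)
        p = est.predict_proba(X)
        assert p.shape == (28, 7)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_cnn_forward_on_single_sample_batch(self):
        X, y = _toy_sequences(n_per_class=3, n_classes=2)
        est = md.CNNClassifier(conv_channels=(2, 2), dense_units=(4,),
                               max_epochs=1, random_state=0)
        est.fit(X, y)
        assert est.predict(X[:1]).shape == (1,)

    def test_untrained_model_is_at_chance_on_random_labels(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(210, 5, 3))
        y = np.repeat([f"c{k}" for k in range(7)], 30)
        est = md.LSTMClassifier(hidden_units=(5,), max_epochs=1,
                                learning_rate=0.0, random_state=1)
        est.fit(X, y)
        acc = est.score(X, rng.permutation(y))
        assert abs(acc - 1 / 7) < 0.12

    def test_convergence_on_separable_data(self):
        X, y = _toy_sequences(seed=4)
        est = md.LSTMClassifier(hidden_units=(8,), max_epochs=60, patience=59,
                                batch_size=16, random_state=0)
        est.fit(X, y)
        # early epochs show a clear downward loss trend
        assert est.loss_history_[5] < est.loss_history_[0]
        assert est.score(X, y) == 1.0

    def test_patience_stops_early_when_loss_is_flat(self):
        X, y = _toy_sequences(n_per_class=5)
        est = md.LSTMClassifier(hidden_units=(4,), max_epochs=100, patience=3,
                                learning_rate=0.0, random_state=0)
        est.fit(X, y)
        assert est.n_epochs_ == 5  # 1 best + patience+1 flat epochs

    def test_same_seed_reproduces_identical_weights(self):
        X, y = _toy_sequences(n_per_class=6)
        runs = []
        for _ in range(2):
            est = md.LSTMClassifier(hidden_units=(6,), max_epochs=5, random_state=42)
            est.fit(X, y)
            runs.append([p.copy() for p in est.net_.params])
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a, b)

    def test_empty_training_set_rejected(self):
        est = md.RNNClassifier(hidden_units=(3,))
        with pytest.raises(ValueError, match="empty"):
            est.fit(np.empty((0, 4, 2)), np.empty(0))

    def test_sklearn_params_round_trip(self):
        est = md.LSTMClassifier(hidden_units=(9,), learning_rate=0.01)
        from sklearn.base import clone
        c = clone(est)
        assert c.get_params()["hidden_units"] == (9,)
        c.set_params(max_epochs=7)
        assert c.max_epochs == 7


class TestSpecsAndTrain:
    def test_build_model_defaults(self):
        assert md.build_model(md.ModelSpec("cnn")).conv_channels == (250, 250, 100)
        assert md.build_model(md.ModelSpec("rnn")).hidden_units == (300, 150, 100)
        assert md.build_model(md.ModelSpec("lstm")).hidden_units == (250, 300, 300)
        with pytest.raises(ValueError, match="unknown model kind"):
            md.ModelSpec("gru")

    def test_train_config_validation_and_history(self):
        with pytest.raises(ValueError, match="patience"):
            md.TrainConfig(max_epochs=10, patience=10)
        X, y = _toy_sequences(n_per_class=4)
        model = md.LSTMClassifier(hidden_units=(4,))
        cfg = md.TrainConfig(max_epochs=3, patience=2, seed=5)
        model, hist = md.train(model, X, y, config=cfg)
        assert len(hist) == 3 and model.n_epochs_ == 3


class TestSubjectGroupedCV:
    def _data(self, n_subjects=16, per_subject=4, seed=0):
        rng = np.random.default_rng(seed)
        n = n_subjects * per_subject
        X = rng.normal(size=(n, 3, 2))
        y = rng.choice(["a", "b"], size=n)
        subjects = np.repeat([f"S{i:02d}" for i in range(n_subjects)], per_subject)
        return X, y, subjects

    def test_fold_structure_with_16_subjects_and_10_folds(self):
        X, y, subjects = self._data()
        est = md.LSTMClassifier(hidden_units=(2,), max_epochs=1, random_state=0)
        res = md.subject_grouped_cv(X, y, subjects, est, folds=10, iterations=2, seed=3)
        for groups in res.fold_subjects:
            sizes = sorted(len(g) for g in groups)
            assert sizes == [1, 1, 1, 1, 2, 2, 2, 2, 2, 2]
            flat = [s for g in groups for s in g]
            assert sorted(flat) == sorted(set(subjects))  # disjoint, exhaustive

    def test_no_subject_leakage_and_confusion_totals(self):
        X, y, subjects = self._data(n_subjects=6, per_subject=3)
        est = md.LSTMClassifier(hidden_units=(2,), max_epochs=1, random_state=0)
        res = md.subject_grouped_cv(X, y, subjects, est, folds=3, iterations=2, seed=1)
        assert res.confusion_.to_numpy().sum() == 2 * len(y)
        assert 0.0 <= res.mean_accuracy <= 100.0

    def test_too_few_subjects_suggests_loso(self):
        X, y, subjects = self._data(n_subjects=4)
        est = md.LSTMClassifier(hidden_units=(2,), max_epochs=1)
        with pytest.raises(ValueError, match="loso"):
            md.subject_grouped_cv(X, y, subjects, est, folds=10)
        res = md.subject_grouped_cv(X, y, subjects, est, folds="loso", iterations=1)
        assert res.fold_accuracies.shape == (1, 4)

    def test_confusion_rendering(self):
        X, y, subjects = self._data(n_subjects=4, per_subject=6, seed=2)
        est = md.LSTMClassifier(hidden_units=(3,), max_epochs=2, random_state=0)
        res = md.subject_grouped_cv(X, y, subjects, est, folds=2, iterations=1)
        cm = md.confusion(res)
        assert list(cm.index) == list(res.labels)
        norm = md.confusion(res, normalize=True)
        rows = norm.sum(axis=1)
        np.testing.assert_allclose(rows[cm.sum(axis=1) > 0], 1.0)


def test_experiment_grid_shape_and_determinism(small_corpus):
    layers = {"lstm": (6,), "rnn": (6,)}
    kw = dict(
        corpus=small_corpus, sets=("PU",), error_rates=(0.05,),
        kinds=("lstm", "rnn"), class_subsets=(4,), layers=layers,
        folds=2, iterations=1, seed=9,
        train_params={"max_epochs": 2, "batch_size": 16},
    )
    t1 = md.run_experiment_grid(**kw)
    t2 = md.run_experiment_grid(**kw)
    assert len(t1) == 2
    assert t1["best_in_group"].sum() == 1
    assert t1.equals(t2)
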