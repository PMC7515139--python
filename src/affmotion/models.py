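"""Sequence classifiers (CNN, plain RNN, RNN-LSTM), the training protocol,
subject-grouped cross-validation, and evaluation reports.

The three architectures consume a padded (keyframes x features) matrix per
recording and emit a softmax distribution over emotion classes.  Reference
layer widths: CNN — three 3x3 convolution layers of 250, 250 and 100
channels, each followed by 2x2 max pooling, then a dense layer of 100
units; plain RNN — recurrent layers of 300, 150, 100 units; LSTM —
recurrent layers of 250, 300, 300 units; all ending in a dense softmax
output layer.  Training uses Adam on cross-entropy for up to 500 epochs
with early stopping after 30 epochs without training-loss improvement
(minimum delta 1e-4).  Recurrent models skip padded timesteps through the
mask; the CNN consumes zero rows as-is.

Evaluation is subject-grouped cross-validation: folds partition *subjects*
so no individual contributes to both the training and test side of a fold.
With 16 subjects and 10 folds, six folds hold two subjects and four hold
one; ``folds="loso"`` gives strict leave-one-subject-out.  Z-score
statistics are fit on the training subjects of each fold by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone

from . import _nn
from .normalize import SequenceStandardizer
from .skeleton import EMOTIONS

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "CVResult",
    "CNNClassifier",
    "RNNClassifier",
    "LSTMClassifier",
    "build_model",
    "train",
    "subject_grouped_cv",
    "confusion",
    "run_experiment_grid",
]

_DEFAULT_LAYERS = {
    "cnn": (250, 250, 100),
    "rnn": (300, 150, 100),
    "lstm": (250, 300, 300),
}


@dataclass(frozen=True)
class ModelSpec:
    """Architecture choice: kind, layer widths, class count, input shape."""

    kind: str
    layers: tuple[int, ...] = ()
    n_classes: int = 7
    input_shape: tuple[int, int] | None = None
    dense_units: tuple[int, ...] = (100,)  # cnn only

    def __post_init__(self):
        if self.kind not in _DEFAULT_LAYERS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not self.layers:
            object.__setattr__(self, "layers", _DEFAULT_LAYERS[self.kind])
        if self.n_classes not in (7, 6, 4) and self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol parameters."""

    optimizer: str = "adam"
    loss: str = "cross_entropy"
    max_epochs: int = 500
    patience: int = 30
    min_delta: float = 1e-4
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if not (self.patience < self.max_epochs):
            raise ValueError("patience must be smaller than max_epochs")


class _SequenceNetClassifier(BaseEstimator, ClassifierMixin):
    """Shared fit/predict machinery for the three sequence classifiers.

    ``X`` is (n_sequences, max_len, n_features); an optional boolean
    ``mask`` (n_sequences, max_len) marks real rows (True prefix).
    """

    def __init__(self, max_epochs=500, patience=30, min_delta=1e-4,
                 learning_rate=1e-3, batch_size=32, clip_norm=5.0,
                 random_state=0):
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_delta = min_delta
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.clip_norm = clip_norm
        self.random_state = random_state

    def _build_net(self, input_shape, n_classes, rng):  # pragma: no cover
        raise NotImplementedError

    def _validate_X(self, X, mask):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("X must be 3-D (n_sequences, max_len, n_features)")
        if mask is None:
            mask = np.ones(X.shape[:2], dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != X.shape[:2]:
                raise ValueError("mask shape must match X[:, :, 0]")
        return X, mask

    def fit(self, X, y, mask=None):
        X, mask = self._validate_X(X, mask)
        y = np.asarray(y)
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        rng = np.random.default_rng(self.random_state)
        self.net_ = self._build_net(X.shape[1:], len(self.classes_), rng)
        opt = _nn.Adam(self.net_.params, lr=self.learning_rate)

        n = X.shape[0]
        history: list[float] = []
        best = np.inf
        wait = 0
        for _epoch in range(self.max_epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, self.batch_size):
                b = order[start:start + self.batch_size]
                logits = self.net_.forward(X[b], mask[b])
                loss, dlogits = _nn.cross_entropy(logits, y_idx[b])
                self.net_.backward(dlogits)
                grads = self.net_.grads
                if self.clip_norm:
                    _nn.clip_global_norm(grads, self.clip_norm)
                opt.step(grads)
                total += loss * len(b)
            epoch_loss = total / n
            history.append(epoch_loss)
            if epoch_loss < best - self.min_delta:
                best = epoch_loss
                wait = 0
            else:
                wait += 1
                if wait > self.patience:
                    break
        self.loss_history_ = np.asarray(history)
        self.n_epochs_ = len(history)
        self.n_features_in_ = X.shape[2]
        return self

    def decision_function(self, X, mask=None):
        X, mask = self._validate_X(X, mask)
        if X.shape[2] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[2]} features, expected {self.n_features_in_}"
            )
        out = np.empty((X.shape[0], len(self.classes_)))
        # bounded batches keep conv im2col memory flat
        for start in range(0, X.shape[0], 256):
            sl = slice(start, start + 256)
            out[sl] = self.net_.forward(X[sl], mask[sl])
        return out

    def predict_proba(self, X, mask=None):
        return _nn.softmax(self.decision_function(X, mask))

    def predict(self, X, mask=None):
        return self.classes_[np.argmax(self.decision_function(X, mask), axis=1)]

    def score(self, X, y, mask=None):
        return float(np.mean(self.predict(X, mask) == np.asarray(y)))


class CNNClassifier(_SequenceNetClassifier):
    """Convolutional classifier over the keyframes x features matrix."""

    def __init__(self, conv_channels=(250, 250, 100), dense_units=(100,),
                 max_epochs=500, patience=30, min_delta=1e-4,
                 learning_rate=1e-3, batch_size=32, clip_norm=5.0,
                 random_state=0):
        super().__init__(max_epochs, patience, min_delta, learning_rate,
                         batch_size, clip_norm, random_state)
        self.conv_channels = conv_channels
        self.dense_units = dense_units

    def _build_net(self, input_shape, n_classes, rng):
        return _nn.ConvNet(input_shape, self.conv_channels, self.dense_units,
                           n_classes, rng)


class RNNClassifier(_SequenceNetClassifier):
    """Plain tanh recurrent classifier (gradient-clipped)."""

    def __init__(self, hidden_units=(300, 150, 100),
                 max_epochs=500, patience=30, min_delta=1e-4,
                 learning_rate=1e-3, batch_size=32, clip_norm=5.0,
                 random_state=0):
        super().__init__(max_epochs, patience, min_delta, learning_rate,
                         batch_size, clip_norm, random_state)
        self.hidden_units = hidden_units

    def _build_net(self, input_shape, n_classes, rng):
        return _nn.RecurrentNet(input_shape[1], self.hidden_units, n_classes,
                                rng, cell="rnn")


class LSTMClassifier(_SequenceNetClassifier):
    """LSTM recurrent classifier."""

    def __init__(self, hidden_units=(250, 300, 300),
                 max_epochs=500, patience=30, min_delta=1e-4,
                 learning_rate=1e-3, batch_size=32, clip_norm=5.0,
                 random_state=0):
        super().__init__(max_epochs, patience, min_delta, learning_rate,
                         batch_size, clip_norm, random_state)
        self.hidden_units = hidden_units

    def _build_net(self, input_shape, n_classes, rng):
        return _nn.RecurrentNet(input_shape[1], self.hidden_units, n_classes,
                                rng, cell="lstm")


def build_model(spec: ModelSpec, config: TrainConfig | None = None):
    """Instantiate the classifier described by a :class:`ModelSpec`."""
    config = config or TrainConfig()
    common = dict(
        max_epochs=config.max_epochs, patience=config.patience,
        min_delta=config.min_delta, learning_rate=config.learning_rate,
        batch_size=config.batch_size, random_state=config.seed,
    )
    if spec.kind == "cnn":
        return CNNClassifier(conv_channels=spec.layers,
                             dense_units=spec.dense_units, **common)
    if spec.kind == "rnn":
        return RNNClassifier(hidden_units=spec.layers, **common)
    return LSTMClassifier(hidden_units=spec.layers, **common)


def train(model, X, y, mask=None, config: TrainConfig | None = None):
    """Fit ``model`` under a :class:`TrainConfig`; returns (model, loss history)."""
    if config is not None:
        model.set_params(
            max_epochs=config.max_epochs, patience=config.patience,
            min_delta=config.min_delta, learning_rate=config.learning_rate,
            batch_size=config.batch_size, random_state=config.seed,
        )
    model.fit(X, y, mask=mask)
    return model, model.loss_history_


@dataclass
class CVResult:
    """Cross-validation outcome.

    ``mean_accuracy`` is in percent, sample-weighted within each iteration
    and averaged over iterations.  ``confusion_`` counts are summed over
    all folds and iterations (rows = true class, columns = predicted).
    """

    labels: tuple[str, ...]
    fold_accuracies: np.ndarray  # (iterations, folds)
    iteration_accuracies: np.ndarray  # (iterations,)
    mean_accuracy: float  # percent
    confusion_: pd.DataFrame
    fold_subjects: list[list[list[str]]] = field(default_factory=list)

    @property
    def per_class_accuracy(self) -> pd.Series:
        cm = self.confusion_.to_numpy().astype(float)
        totals = cm.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = np.where(totals > 0, np.diag(cm) / totals, np.nan)
        return pd.Series(acc, index=self.confusion_.index)


def _canonical_labels(y) -> tuple[str, ...]:
    present = set(np.asarray(y).tolist())
    ordered = [e for e in EMOTIONS if e in present]
    extra = sorted(present - set(ordered))
    return tuple(ordered + extra)


def subject_grouped_cv(
    X,
    y,
    subjects,
    estimator,
    mask=None,
    folds: int | str = 10,
    iterations: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> CVResult:
    """Subject-grouped k-fold cross-validation.

    Folds partition the set of subjects; every subject appears in exactly
    one test fold per iteration, and fold assignment is reshuffled per
    iteration.  ``folds="loso"`` uses one fold per subject.  With
    ``standardize=True`` (default) per-feature z-score statistics are fit
    on the training rows of each fold and applied to its test rows.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    subjects = np.asarray(subjects)
    if mask is None:
        mask = np.ones(X.shape[:2], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    uniq = np.unique(subjects)
    if folds == "loso":
        folds = len(uniq)
    folds = int(folds)
    if len(uniq) < folds:
        raise ValueError(
            f"{len(uniq)} subjects < {folds} folds; use folds='loso' for strict "
            "leave-one-subject-out"
        )
    labels = _canonical_labels(y)
    lab_idx = {l: i for i, l in enumerate(labels)}
    cm = np.zeros((len(labels), len(labels)), dtype=np.int64)
    rng = np.random.default_rng(seed)

    fold_acc = np.zeros((iterations, folds))
    iter_acc = np.zeros(iterations)
    fold_subjects: list[list[list[str]]] = []
    for it in range(iterations):
        perm = rng.permutation(uniq)
        groups = np.array_split(perm, folds)
        fold_subjects.append([list(map(str, g)) for g in groups])
        correct = 0
        total = 0
        for fi, test_subj in enumerate(groups):
            test_set = set(test_subj.tolist())
            is_test = np.isin(subjects, test_subj)
            tr, te = ~is_test, is_test
            assert not (set(subjects[tr]) & test_set), "subject leakage"
            Xtr, Xte = X[tr], X[te]
            if standardize:
                std = SequenceStandardizer()
                std.fit(Xtr, mask=mask[tr])
                Xtr = std.transform(Xtr, mask=mask[tr])
                Xte = std.transform(Xte, mask=mask[te])
            est = clone(estimator)
            est.set_params(random_state=int(rng.integers(2 ** 31 - 1)))
            est.fit(Xtr, y[tr], mask=mask[tr])
            pred = est.predict(Xte, mask=mask[te])
            hits = pred == y[te]
            fold_acc[it, fi] = float(np.mean(hits))
            correct += int(hits.sum())
            total += len(hits)
            for t, p in zip(y[te], pred):
                cm[lab_idx[t], lab_idx[p]] += 1
        iter_acc[it] = correct / total
    cm_df = pd.DataFrame(cm, index=pd.Index(labels, name="true"),
                         columns=pd.Index(labels, name="predicted"))
    return CVResult(
        labels=labels, fold_accuracies=fold_acc, iteration_accuracies=iter_acc,
        mean_accuracy=float(iter_acc.mean() * 100.0), confusion_=cm_df,
        fold_subjects=fold_subjects,
    )


def confusion(result: CVResult, normalize: bool = False) -> pd.DataFrame:
    """Confusion matrix in canonical label order; optionally row-normalized."""
    cm = result.confusion_.copy()
    if normalize:
        totals = cm.sum(axis=1).replace(0, 1)
        cm = cm.div(totals, axis=0)
    return cm


def run_experiment_grid(
    corpus,
    sets=("P",),
    error_rates=(0.03,),
    kinds=("lstm",),
    class_subsets=(7,),
    layers: dict | None = None,
    folds: int | str = 10,
    iterations: int = 1,
    seed: int = 0,
    train_params: dict | None = None,
) -> pd.DataFrame:
    """Mean CV accuracy per (network, feature set, error rate, class subset).

    Preprocessing is shared across class subsets: the dataset for each
    (set, error rate) pair is built once and rows are filtered to the
    subset's labels.  ``layers`` optionally maps kind -> layer widths
    (defaults to the reference widths, which are large; pass smaller ones
    for desk-scale runs).  Returns a tidy DataFrame with a
    ``best_in_group`` flag marking the top accuracy within each
    (set, error rate, subset) column.
    """
    from .pipeline import prepare_dataset
    from .skeleton import SIX_CLASS_SUBSET, FOUR_CLASS_SUBSET

    subset_labels = {7: EMOTIONS, 6: SIX_CLASS_SUBSET, 4: FOUR_CLASS_SUBSET}
    rows = []
    for set_id in sets:
        for eps in error_rates:
            ds = prepare_dataset(corpus, set_id=set_id, error_rate=eps, zscore=False)
            for n_cls in class_subsets:
                keep = np.isin(ds["labels"], subset_labels[n_cls])
                for kind in kinds:
                    spec_layers = (layers or {}).get(kind, _DEFAULT_LAYERS[kind])
                    spec = ModelSpec(kind=kind, layers=tuple(spec_layers), n_classes=n_cls)
                    est = build_model(spec)
                    if train_params:
                        est.set_params(**train_params)
                    res = subject_grouped_cv(
                        ds["X"][keep], ds["labels"][keep], ds["subjects"][keep],
                        est, mask=ds["mask"][keep], folds=folds,
                        iterations=iterations, seed=seed,
                    )
                    rows.append({
                        "network": kind, "set": set_id, "error_rate": eps,
                        "n_classes": n_cls, "accuracy": res.mean_accuracy,
                    })
    table = pd.DataFrame(rows)
    table["best_in_group"] = False
    for _, idx in table.groupby(["set", "error_rate", "n_classes"]).groups.items():
        best = table.loc[idx, "accuracy"].idxmax()
        table.loc[best, "best_in_group"] = True
    return table
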