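"""Feed-forward intake classifier (38-5-1, tanh/tanh) and its evaluation.

A three-layer network maps the 38-feature epoch vector to a single output
in (-1, 1); the predicted class is its sign (food intake = +1).  Both the
hidden layer (5 units by default) and the output unit use the hyperbolic
tangent.  Training is gradient-based back-propagation (full-batch Adam on
the squared error to the +/-1 targets) with early stopping on a 10%
validation split of the training data, seed-controlled throughout.

Features are z-scored with statistics from the training data only — tanh
units saturate on raw amplitude-scale features — and the scaler travels
with the model.

Model selection and evaluation follow the subject-wise protocol: the
hidden-layer size is chosen by repeated k-fold cross-validation over sizes
1..15, and generalisation is measured with leave-one-subject-out (LOSO)
cross-validation scored by the F1 of the intake class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from sklearn.model_selection import KFold

from .features import FEATURE_NAMES, N_FEATURES

DEFAULT_N_HIDDEN = 5
MAX_ITER = 500
EARLY_STOP_PATIENCE = 25
VALIDATION_FRACTION = 0.10
ADAM_LR = 0.02


@dataclass
class ClassMetrics:
    """Confusion counts and derived scores for the intake (+1) class.

    Zero-denominator conventions: precision/recall are 0 when undefined and
    F1 is 0 when precision + recall = 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def classification_metrics(predicted: Sequence[int], truth: Sequence[int]) -> ClassMetrics:
    """TP/FP/FN/TN counts with intake (+1) as the positive class."""
    pred = np.asarray(predicted, dtype=int)
    true = np.asarray(truth, dtype=int)
    if pred.shape != true.shape:
        raise ValueError("predicted and truth must have equal length")
    valid = {-1, 1}
    if not set(pred.tolist()) <= valid or not set(true.tolist()) <= valid:
        raise ValueError("labels must be +1 or -1")
    return ClassMetrics(
        tp=int(np.sum((pred == 1) & (true == 1))),
        fp=int(np.sum((pred == 1) & (true == -1))),
        fn=int(np.sum((pred == -1) & (true == 1))),
        tn=int(np.sum((pred == -1) & (true == -1))),
    )


@dataclass
class AnnModel:
    """Trained 38-h-1 network with its feature scaler."""

    w1: np.ndarray  # (n_features, n_hidden)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden, 1)
    b2: np.ndarray  # (1,)
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    n_hidden: int
    seed: int
    feature_names: List[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    loss_curve: List[float] = field(default_factory=list)

    def _scale(self, x: np.ndarray) -> np.ndarray:
        return (x - self.scaler_mean) / self.scaler_std

    def raw_output(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != self.w1.shape[0]:
            raise ValueError(
                f"expected {self.w1.shape[0]} features, got {x.shape[1]}"
            )
        z = self._scale(x)
        hidden = np.tanh(z @ self.w1 + self.b1)
        return np.tanh(hidden @ self.w2 + self.b2)[:, 0]

    def to_json(self, path) -> None:
        payload = {
            "architecture": [self.w1.shape[0], self.n_hidden, 1],
            "activation": "tanh",
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_std": self.scaler_std.tolist(),
            "seed": self.seed,
            "feature_names": self.feature_names,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "AnnModel":
        d = json.loads(Path(path).read_text())
        return cls(
            w1=np.asarray(d["w1"]),
            b1=np.asarray(d["b1"]),
            w2=np.asarray(d["w2"]),
            b2=np.asarray(d["b2"]),
            scaler_mean=np.asarray(d["scaler_mean"]),
            scaler_std=np.asarray(d["scaler_std"]),
            n_hidden=d["architecture"][1],
            seed=d["seed"],
            feature_names=d["feature_names"],
        )


def _forward(x, w1, b1, w2, b2):
    h = np.tanh(x @ w1 + b1)
    out = np.tanh(h @ w2 + b2)
    return h, out


def train_ann(
    features: np.ndarray,
    labels: Sequence[int],
    n_hidden: int = DEFAULT_N_HIDDEN,
    seed: int = 0,
    max_iter: int = MAX_ITER,
) -> AnnModel:
    """Train the tanh/tanh network with back-propagation.

    Deterministic for a fixed seed.  Requires at least two examples of each
    class.  Early stopping monitors the squared-error loss on a held-out
    10% validation split of the training data.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).reshape(-1, 1)
    if x.ndim != 2:
        raise ValueError("features must be 2-D")
    if x.shape[0] != y.shape[0]:
        raise ValueError("features and labels must have equal length")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    if counts.min() < 2:
        raise ValueError("need at least two examples per class")

    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std = np.where(std == 0, 1.0, std)
    z = (x - mean) / std

    rng = np.random.default_rng(seed)
    n, d = z.shape
    perm = rng.permutation(n)
    n_val = max(1, int(round(VALIDATION_FRACTION * n)))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    # keep both classes in the optimisation set
    if len(np.unique(y[train_idx])) < 2:
        train_idx, val_idx = perm, perm[:n_val]
    zt, yt = z[train_idx], y[train_idx]
    zv, yv = z[val_idx], y[val_idx]

    # Glorot-style initialisation
    w1 = rng.normal(0, np.sqrt(2.0 / (d + n_hidden)), size=(d, n_hidden))
    b1 = np.zeros(n_hidden)
    w2 = rng.normal(0, np.sqrt(2.0 / (n_hidden + 1)), size=(n_hidden, 1))
    b2 = np.zeros(1)

    params = [w1, b1, w2, b2]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    best = [p.copy() for p in params]
    best_val = np.inf
    stall = 0
    loss_curve: List[float] = []

    for it in range(1, max_iter + 1):
        h, out = _forward(zt, *params)
        err = out - yt
        loss = float(np.mean(err**2))
        loss_curve.append(loss)

        # back-propagation through the two tanh layers
        g_out = 2.0 * err * (1 - out**2) / len(zt)
        g_w2 = h.T @ g_out
        g_b2 = g_out.sum(axis=0)
        g_h = g_out @ params[2].T * (1 - h**2)
        g_w1 = zt.T @ g_h
        g_b1 = g_h.sum(axis=0)
        grads = [g_w1, g_b1, g_w2, g_b2]

        for j, g in enumerate(grads):
            m[j] = beta1 * m[j] + (1 - beta1) * g
            v[j] = beta2 * v[j] + (1 - beta2) * g**2
            mhat = m[j] / (1 - beta1**it)
            vhat = v[j] / (1 - beta2**it)
            params[j] -= ADAM_LR * mhat / (np.sqrt(vhat) + eps)

        _, out_v = _forward(zv, *params)
        val_loss = float(np.mean((out_v - yv) ** 2))
        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best = [p.copy() for p in params]
            stall = 0
        else:
            stall += 1
            if stall >= EARLY_STOP_PATIENCE:
                break

    w1, b1, w2, b2 = best
    return AnnModel(
        w1=w1,
        b1=b1,
        w2=w2,
        b2=b2,
        scaler_mean=mean,
        scaler_std=std,
        n_hidden=n_hidden,
        seed=seed,
        loss_curve=loss_curve,
    )


def predict(model: AnnModel, features: np.ndarray) -> np.ndarray:
    """Class labels in {-1, +1}; a raw output of exactly 0 breaks to +1."""
    x = np.asarray(features, dtype=float)
    if x.size == 0:
        return np.empty(0, dtype=int)
    out = model.raw_output(x)
    return np.where(out >= 0, 1, -1).astype(int)


SubjectData = Mapping[str, Tuple[np.ndarray, np.ndarray]]


@dataclass
class LosoResult:
    per_subject: Dict[str, ClassMetrics]
    per_subject_f1: Dict[str, float]
    mean_f1: float
    std_f1: float
    mean_precision: float
    mean_recall: float


def loso_cv(
    dataset: SubjectData,
    n_hidden: int = DEFAULT_N_HIDDEN,
    seeds: Sequence[int] = (0,),
) -> LosoResult:
    """Leave-one-subject-out cross-validation.

    Each subject is held out once; a model is trained on the pooled data of
    the remaining subjects (per seed in ``seeds``) and scored on the
    held-out subject.  Per-subject F1 is averaged over seeds; the reported
    confusion counts come from the first seed.  Feature scaling is fitted
    inside :func:`train_ann`, on the training fold only.
    """
    subjects = list(dataset.keys())
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least two subjects")
    for s in subjects:
        if len(dataset[s][0]) == 0:
            raise ValueError(f"subject {s!r} has no epochs")

    per_subject: Dict[str, ClassMetrics] = {}
    per_subject_f1: Dict[str, float] = {}
    for held_out in subjects:
        train_x = np.vstack([dataset[s][0] for s in subjects if s != held_out])
        train_y = np.concatenate([dataset[s][1] for s in subjects if s != held_out])
        test_x, test_y = dataset[held_out]
        f1s = []
        for k, seed in enumerate(seeds):
            model = train_ann(train_x, train_y, n_hidden=n_hidden, seed=seed)
            metrics = classification_metrics(predict(model, test_x), test_y)
            if k == 0:
                per_subject[held_out] = metrics
            f1s.append(metrics.f1)
        per_subject_f1[held_out] = float(np.mean(f1s))

    f1_values = np.array(list(per_subject_f1.values()))
    return LosoResult(
        per_subject=per_subject,
        per_subject_f1=per_subject_f1,
        mean_f1=float(f1_values.mean()),
        std_f1=float(f1_values.std(ddof=1)) if len(f1_values) > 1 else 0.0,
        mean_precision=float(np.mean([m.precision for m in per_subject.values()])),
        mean_recall=float(np.mean([m.recall for m in per_subject.values()])),
    )


def select_hidden_units(
    features: np.ndarray,
    labels: Sequence[int],
    k_range: Sequence[int] = tuple(range(1, 16)),
    n_folds: int = 30,
    n_reps: int = 10,
    seed: int = 0,
    tolerance: float = 0.005,
) -> Tuple[int, Dict[int, float]]:
    """Pick the hidden-layer size by repeated k-fold cross-validation.

    For each candidate size the mean F1 over ``n_folds`` folds x ``n_reps``
    repetitions (fresh shuffles and initialisations per repetition) is
    computed.  The chosen size is the smallest whose mean F1 is within
    ``tolerance`` of the maximum — the explicit form of the elbow rule
    "gains are small beyond 5 hidden units".  ``tolerance=0`` degenerates
    to the argmax (smallest argmax on ties).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if n_folds > len(x):
        raise ValueError("more folds than examples")
    if len(k_range) == 0:
        raise ValueError("empty size range")

    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_reps)]

    table: Dict[int, float] = {}
    for k in k_range:
        f1s = []
        for rep_seed in rep_seeds:
            kf = KFold(n_splits=n_folds, shuffle=True, random_state=rep_seed)
            for train_idx, test_idx in kf.split(x):
                model = train_ann(x[train_idx], y[train_idx], n_hidden=k, seed=rep_seed)
                metrics = classification_metrics(predict(model, x[test_idx]), y[test_idx])
                f1s.append(metrics.f1)
        table[int(k)] = float(np.mean(f1s))

    best = max(table.values())
    chosen = min(k for k, f1 in table.items() if f1 >= best - tolerance)
    return chosen, table
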