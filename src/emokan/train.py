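"""Training protocol, 10-fold cross-validation and weighted evaluation metrics.

The optimiser is Adam (lr 5e-4, batch 512) minimising categorical
cross-entropy plus an L2 penalty (0.001) on kernel weights.  Cross-validation
shuffles at the sample level with a fixed seed; per-fold data preparation
(min-max fitting, baseline correction) is injected through a ``prepare``
callback so that nothing is fitted outside a fold's training split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .errors import TrainingDivergedError
from .models import ModelConfig, build_model
from .nn import Adam, Network, softmax_cross_entropy


@dataclass
class TrainConfig:
    lr: float = 0.0005
    batch_size: int = 512
    epochs: int = 200
    l2: float = 0.001
    seed: int = 2024
    folds: int = 10

    def __post_init__(self) -> None:
        if self.folds < 2 or min(self.lr, self.batch_size, self.epochs) < 0:
            raise ValueError("folds >= 2 and nonnegative lr/batch/epochs required")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class FoldResult:
    fold_index: int
    accuracy: float
    precision: float  # support-weighted
    recall: float
    f1: float
    per_class: dict = field(default_factory=dict)
    n_test: int = 0
    normalization_tag: str = ""

    def as_dict(self) -> dict:
        return {
            "fold": self.fold_index, "accuracy": self.accuracy,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "n_test": self.n_test,
        }


def kfold_split(n_samples: int, folds: int, seed: int) -> np.ndarray:
    """Seeded shuffled K-fold partition; returns the test-fold id of each sample."""
    if n_samples < folds:
        raise ValueError(f"cannot split {n_samples} samples into {folds} folds")
    assignment = np.empty(n_samples, dtype=int)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(kf.split(np.arange(n_samples))):
        assignment[test_idx] = fold
    return assignment


def train_fold(model: Network, x_train: np.ndarray, y_train: np.ndarray,
               config: TrainConfig, x_val=None, y_val=None) -> dict:
    """Minibatch Adam training; returns the per-epoch history."""
    if len(x_train) == 0:
        raise ValueError("empty training data")
    x_train = np.asarray(x_train, dtype=np.float32)
    y_train = np.asarray(y_train, dtype=np.int64)
    opt = Adam(model.params(), lr=config.lr, l2=config.l2)
    rng = np.random.default_rng(config.seed)
    history = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
    n = len(x_train)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = model.forward(xb, training=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            loss += opt.penalty()
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, step {start // config.batch_size}"
                )
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
            epoch_correct += int((logits.argmax(axis=1) == yb).sum())
        history["loss"].append(epoch_loss / n)
        history["accuracy"].append(epoch_correct / n)
        if x_val is not None:
            proba = model.predict_proba(x_val)
            vl, _ = softmax_cross_entropy(np.log(proba + 1e-12), np.asarray(y_val))
            history["val_loss"].append(vl)
            history["val_accuracy"].append(float((proba.argmax(1) == y_val).mean()))
    return history


def compute_metrics(y_true, y_pred, classes=None) -> dict:
    """Accuracy plus support-weighted one-vs-rest precision / recall / F1.

    Per-class counts follow the one-vs-rest convention: for class c, TP are
    samples of c predicted c, FP are other samples predicted c, FN are
    samples of c predicted otherwise, TN the rest.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be non-empty and equally long")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    n = len(y_true)
    per_class: dict = {}
    weighted = {"precision": 0.0, "recall": 0.0, "f1": 0.0}
    for c in classes:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        counts = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=n - tp - fp - fn)
        per_class[c] = counts
        support = tp + fn
        for key, value in (("precision", counts.precision), ("recall", counts.recall),
                           ("f1", counts.f1)):
            weighted[key] += support * value / n
    return {
        "accuracy": float(np.mean(y_true == y_pred)),
        "precision": weighted["precision"],
        "recall": weighted["recall"],
        "f1": weighted["f1"],
        "per_class": per_class,
    }


def summarize_folds(fold_results: list[FoldResult]) -> dict:
    metrics = ("accuracy", "precision", "recall", "f1")
    out = {}
    for m in metrics:
        values = np.array([getattr(r, m) for r in fold_results])
        out[f"{m}_mean"] = float(values.mean())
        out[f"{m}_std"] = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return out


def run_cv(x, y, model_config: ModelConfig, train_config: TrainConfig,
           prepare=None, builder=build_model):
    """K-fold cross-validation; returns ``(fold_results, summary)``.

    ``prepare(train_idx, test_idx)`` may return
    ``(x_train, y_train, x_test, y_test, tag)`` to perform per-fold feature
    preparation (normalisation fitted on the training split only); by default
    ``x`` is indexed directly.
    """
    y = np.asarray(y)
    n = len(y)
    assignment = kfold_split(n, train_config.folds, train_config.seed)
    results = []
    for fold in range(train_config.folds):
        test_idx = np.flatnonzero(assignment == fold)
        train_idx = np.flatnonzero(assignment != fold)
        if prepare is not None:
            x_tr, y_tr, x_te, y_te, tag = prepare(train_idx, test_idx)
        else:
            x_tr, y_tr, x_te, y_te = x[train_idx], y[train_idx], x[test_idx], y[test_idx]
            tag = f"fold{fold}"
        model = builder(model_config, seed=train_config.seed + fold)
        train_fold(model, x_tr, y_tr, train_config)
        y_pred = model.predict_proba(x_te).argmax(axis=1)
        m = compute_metrics(y_te, y_pred)
        results.append(FoldResult(
            fold_index=fold, accuracy=m["accuracy"], precision=m["precision"],
            recall=m["recall"], f1=m["f1"], per_class=m["per_class"],
            n_test=len(test_idx), normalization_tag=tag,
        ))
    return results, summarize_folds(results)
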