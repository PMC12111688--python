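"""End-to-end pipeline: trials -> features -> correction -> images -> CV.

The public surface follows the model/results idiom: an
:class:`EmotionClassifier` is built from trials (or a precomputed feature
table), ``fit()`` runs seeded K-fold cross-validation with per-fold min-max
fitting, and returns a :class:`CVResults` carrying per-fold metrics, their
mean and spread, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bands import FeatureExtractor
from .baseline import MinMaxNormalizer, TrialFeatures, correct, split_baseline
from .mapping import window_to_image
from .models import ModelConfig, build_model
from .train import (
    FoldResult,
    TrainConfig,
    compute_metrics,
    kfold_split,
    run_cv,
    summarize_folds,
    train_fold,
)


@dataclass
class FeatureTable:
    """Per-window features of a dataset, with trial bookkeeping.

    ``values`` holds the raw (uncorrected) 48-vector of every experimental
    window; baseline features are kept per trial for the correction stage.
    """

    values: np.ndarray  # (n_windows, 48) experimental windows
    labels: np.ndarray  # (n_windows,) class labels (original dtype)
    trial_index: np.ndarray  # (n_windows,) index into trials
    trials: list  # list[TrialFeatures]
    classes: np.ndarray = field(init=False)
    y: np.ndarray = field(init=False)  # integer class codes

    def __post_init__(self) -> None:
        self.classes, self.y = np.unique(self.labels, return_inverse=True)

    @classmethod
    def from_trials(cls, trials, extractor: FeatureExtractor | None = None,
                    window_seconds: float = 1.0) -> "FeatureTable":
        extractor = extractor or FeatureExtractor()
        rows, labels, trial_index, tfs = [], [], [], []
        for ti, trial in enumerate(trials):
            base_w, expe_w = split_baseline(trial, window_seconds)
            base_f = [extractor(w, window_index=i, trial_id=trial.trial_id,
                                is_baseline=True, label=trial.label)
                      for i, w in enumerate(base_w)]
            expe_f = [extractor(w, window_index=i, trial_id=trial.trial_id,
                                label=trial.label)
                      for i, w in enumerate(expe_w)]
            tfs.append(TrialFeatures(base_f, expe_f, trial.trial_id, trial.label))
            for w in expe_f:
                rows.append(w.values)
                labels.append(trial.label)
                trial_index.append(ti)
        return cls(np.stack(rows), np.asarray(labels), np.asarray(trial_index), tfs)

    def __len__(self) -> int:
        return len(self.values)

    def baseline_matrix(self, trial_ids) -> np.ndarray:
        """Raw baseline features of the given trials, stacked row-wise."""
        rows = [w.values for ti in trial_ids for w in self.trials[ti].baseline_windows]
        return np.stack(rows)

    def corrected_images(self, window_idx, normalizer: MinMaxNormalizer) -> np.ndarray:
        """Normalise, baseline-correct and map the given windows to images."""
        scaled = normalizer.transform(self.values[window_idx])
        corrected = np.empty_like(scaled)
        for ti in np.unique(self.trial_index[window_idx]):
            base = normalizer.transform(self.baseline_matrix([ti])).mean(axis=0)
            mask = self.trial_index[window_idx] == ti
            corrected[mask] = correct(scaled[mask], base)
        return np.stack([window_to_image(row) for row in corrected]).astype(np.float32)

    def fit_normalizer(self, window_idx, tag: str = "") -> MinMaxNormalizer:
        """Min-max state fitted on the given windows plus their trials' baselines."""
        trial_ids = np.unique(self.trial_index[window_idx])
        matrix = np.vstack([self.values[window_idx], self.baseline_matrix(trial_ids)])
        return MinMaxNormalizer().fit(matrix, fitted_on=tag)


@dataclass
class CVResults:
    """Cross-validated estimates of the classifier's performance."""

    fold_results: list
    summary_stats: dict
    model_config: ModelConfig
    train_config: TrainConfig
    classes: np.ndarray

    @property
    def accuracy_mean(self) -> float:
        return self.summary_stats["accuracy_mean"]

    @property
    def accuracy_std(self) -> float:
        return self.summary_stats["accuracy_std"]

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame([r.as_dict() for r in self.fold_results])

    def summary(self) -> str:
        s = self.summary_stats
        lines = [
            "Emotion classification — cross-validation results",
            "=" * 58,
            f"variant: {self.model_config.variant}    "
            f"classes: {', '.join(map(str, self.classes))}",
            f"folds: {len(self.fold_results)}    epochs: {self.train_config.epochs}    "
            f"seed: {self.train_config.seed}",
            "-" * 58,
            f"{'fold':>4} {'n_test':>7} {'acc':>8} {'prec':>8} {'rec':>8} {'f1':>8}",
        ]
        for r in self.fold_results:
            lines.append(f"{r.fold_index:>4} {r.n_test:>7} {r.accuracy:>8.4f} "
                         f"{r.precision:>8.4f} {r.recall:>8.4f} {r.f1:>8.4f}")
        lines.append("-" * 58)
        lines.append(
            f"mean     accuracy {s['accuracy_mean']:.4f} ± {s['accuracy_std']:.4f}   "
            f"f1 {s['f1_mean']:.4f} ± {s['f1_std']:.4f}")
        return "\n".join(lines)


class EmotionClassifier:
    """Sparse-channel EEG emotion classifier (model object).

    Built from trials or a :class:`FeatureTable`; ``fit`` runs the full
    cross-validated protocol (per-fold min-max fitting, baseline correction,
    pseudo-RGB mapping, network training) and returns :class:`CVResults`.
    """

    def __init__(self, feature_table: FeatureTable,
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.table = feature_table
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig()
        self.model_ = None
        self.normalizer_ = None

    @classmethod
    def from_trials(cls, trials, variant: str = "cnn_kan_f2ca",
                    model_config: ModelConfig | None = None,
                    train_config: TrainConfig | None = None,
                    **train_overrides) -> "EmotionClassifier":
        table = FeatureTable.from_trials(trials)
        model_config = model_config or ModelConfig(
            variant=variant, num_classes=len(table.classes))
        train_config = train_config or TrainConfig()
        if train_overrides:
            train_config = replace(train_config, **train_overrides)
        return cls(table, model_config, train_config)

    def _prepare_factory(self, y):
        fold_counter = {"i": 0}

        def prepare(train_idx, test_idx):
            tag = f"fold{fold_counter['i']}"
            fold_counter["i"] += 1
            norm = self.table.fit_normalizer(train_idx, tag=tag)
            x_tr = self.table.corrected_images(train_idx, norm)
            x_te = self.table.corrected_images(test_idx, norm)
            return x_tr, y[train_idx], x_te, y[test_idx], tag

        return prepare

    def fit(self, shuffle_labels: bool = False, shuffle_seed: int | None = None) -> CVResults:
        """Run the seeded K-fold protocol; optionally on label-shuffled data
        (the permutation-null control)."""
        y = self.table.y.copy()
        if shuffle_labels:
            rng = np.random.default_rng(
                self.train_config.seed if shuffle_seed is None else shuffle_seed)
            y = rng.permutation(y)
        results, stats = run_cv(
            None, y, self.model_config, self.train_config,
            prepare=self._prepare_factory(y),
        )
        return CVResults(results, stats, self.model_config, self.train_config,
                         self.table.classes)

    def fit_holdout(self, train_frac: float = 0.8, val_frac: float = 0.1):
        """Single 8:1:1 split; trains one final model kept on the instance.

        Returns ``(history, metrics)`` where metrics are computed on the
        held-out test share.
        """
        n = len(self.table)
        rng = np.random.default_rng(self.train_config.seed)
        order = rng.permutation(n)
        n_tr = int(round(train_frac * n))
        n_va = int(round(val_frac * n))
        tr, va, te = order[:n_tr], order[n_tr:n_tr + n_va], order[n_tr + n_va:]
        norm = self.table.fit_normalizer(tr, tag="holdout-train")
        x_tr = self.table.corrected_images(tr, norm)
        x_va = self.table.corrected_images(va, norm)
        x_te = self.table.corrected_images(te, norm)
        y = self.table.y
        model = build_model(self.model_config, seed=self.train_config.seed)
        history = train_fold(model, x_tr, y[tr], self.train_config, x_va, y[va])
        pred = model.predict_proba(x_te).argmax(axis=1)
        self.model_, self.normalizer_ = model, norm
        return history, compute_metrics(y[te], pred)
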