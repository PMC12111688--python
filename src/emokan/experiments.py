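"""Canonical end-to-end experiments on synthetic data.

These functions pin the study conditions used by the test suite and the
reproduction script: a balanced 4-class dataset of 63-s trials at 128 Hz
(60 experimental windows each), the strongly separable generator preset,
and the cross-validated training protocol at desk scale (30 epochs).
"""

from __future__ import annotations

from .models import ModelConfig
from .pipeline import CVResults, EmotionClassifier, FeatureTable
from .synth import default_four_class_config, simulate_dataset
from .train import TrainConfig


def build_feature_table(seed: int, n_trials_per_class: int = 10,
                        effect: float = 3.0) -> FeatureTable:
    """Simulate the canonical 4-class dataset and extract all window features."""
    config = default_four_class_config(effect=effect)
    trials = simulate_dataset(config, n_trials_per_class, seed=seed)
    return FeatureTable.from_trials(trials)


def cross_validate(table: FeatureTable, seed: int, variant: str = "cnn_kan_f2ca",
                   epochs: int = 30, folds: int = 10,
                   shuffle_labels: bool = False) -> CVResults:
    """The full protocol on a prepared feature table (per-fold normalisation)."""
    clf = EmotionClassifier(
        table,
        model_config=ModelConfig(variant=variant, num_classes=len(table.classes)),
        train_config=TrainConfig(epochs=epochs, folds=folds, seed=seed),
    )
    return clf.fit(shuffle_labels=shuffle_labels)


def end_to_end_cv(seed: int, n_trials_per_class: int = 10, epochs: int = 30,
                  folds: int = 10, variant: str = "cnn_kan_f2ca",
                  shuffle_labels: bool = False) -> CVResults:
    """Simulate, extract, correct, map and cross-validate in one call."""
    table = build_feature_table(seed, n_trials_per_class)
    return cross_validate(table, seed, variant=variant, epochs=epochs, folds=folds,
                          shuffle_labels=shuffle_labels)
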