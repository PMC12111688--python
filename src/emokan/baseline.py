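"""Individual-difference correction of window features.

Each trial starts with a short pre-stimulus *baseline* segment (3 s by
default).  Features are min-max normalised to [0, 1] with ranges fitted on a
training split, the per-trial mean of the normalised baseline features is
computed, and that mean is subtracted from every normalised experimental
feature of the trial.  Corrected features therefore lie in [-1, 1] and are
centred on the subject's own resting statistics, which removes a large part
of the between-subject offset before classification.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .bands import EEGWindow, FeatureWindow, feature_names
from .errors import MalformedTrialError
from .trial import EEGTrial


@dataclass
class TrialFeatures:
    """All feature windows of one trial, split into baseline and experimental."""

    baseline_windows: list
    experimental_windows: list
    trial_id: str
    label: object

    def __post_init__(self) -> None:
        if not self.baseline_windows:
            raise MalformedTrialError(f"trial {self.trial_id!r} has no baseline windows")


def split_windows(samples: np.ndarray, fs: float, baseline_seconds: float = 3.0,
                  window_seconds: float = 1.0):
    """Cut a trial's sample matrix into baseline and experimental 1-s windows.

    Returns ``(baseline, experimental)`` lists of (n, n_channels) arrays.
    Raises :class:`MalformedTrialError` if the trial is not longer than its
    baseline.  A trailing partial window is dropped.
    """
    n = samples.shape[0]
    nb = int(round(baseline_seconds * fs))
    nw = int(round(window_seconds * fs))
    if n <= nb:
        raise MalformedTrialError(
            f"trial of {n} samples is not longer than its {nb}-sample baseline"
        )
    baseline = [samples[i:i + nw] for i in range(0, nb - nw + 1, nw)]
    experimental = [samples[i:i + nw] for i in range(nb, n - nw + 1, nw)]
    return baseline, experimental


def split_baseline(trial: EEGTrial, window_seconds: float = 1.0):
    """Split a trial into baseline and experimental 1-s :class:`EEGWindow` lists.

    A 63-s trial at 128 Hz with a 3-s baseline yields 3 baseline and 60
    experimental windows.
    """
    base, expe = split_windows(trial.samples, trial.fs, trial.baseline_seconds, window_seconds)
    to_win = lambda arr: EEGWindow(arr, trial.fs, trial.channel_names)
    return [to_win(b) for b in base], [to_win(e) for e in expe]


def baseline_mean(baseline_values) -> float:
    """Arithmetic mean of a feature over the baseline windows."""
    values = np.asarray(baseline_values, dtype=float)
    if values.size == 0:
        raise MalformedTrialError("baseline mean of an empty list")
    return float(values.mean())


@dataclass
class MinMaxNormalizer:
    """Per-feature min-max scaling to [0, 1], fitted on a training split only.

    Values outside the fitted range are clipped; degenerate features with
    ``f_min == f_max`` map to 0 (with a warning at fit time).
    """

    f_min: np.ndarray | None = None
    f_max: np.ndarray | None = None
    fitted_on: str = ""
    names: list = field(default_factory=feature_names)

    @property
    def is_fitted(self) -> bool:
        return self.f_min is not None

    def fit(self, features: np.ndarray, fitted_on: str = "") -> "MinMaxNormalizer":
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or features.shape[0] < 2:
            raise ValueError("fit needs a 2-D matrix with at least 2 rows")
        self.f_min = features.min(axis=0)
        self.f_max = features.max(axis=0)
        self.fitted_on = fitted_on
        degenerate = np.flatnonzero(self.f_max == self.f_min)
        if degenerate.size:
            names = [self.names[i] if i < len(self.names) else str(i) for i in degenerate]
            warnings.warn(f"degenerate (constant) feature columns map to 0: {names}")
        return self

    def transform(self, features: np.ndarray) -> np.ndarray:
        if not self.is_fitted:
            raise ValueError("normalizer is not fitted")
        features = np.asarray(features, dtype=float)
        span = self.f_max - self.f_min
        safe = np.where(span == 0, 1.0, span)
        scaled = (features - self.f_min) / safe
        scaled = np.where(span == 0, 0.0, scaled)
        return np.clip(scaled, 0.0, 1.0)

    def fit_transform(self, features: np.ndarray, fitted_on: str = "") -> np.ndarray:
        return self.fit(features, fitted_on).transform(features)

    # -- JSON sidecar ------------------------------------------------------
    def to_json(self) -> str:
        if not self.is_fitted:
            raise ValueError("normalizer is not fitted")
        payload = {
            "fitted_on": self.fitted_on,
            "features": {
                name: {"min": float(lo), "max": float(hi)}
                for name, lo, hi in zip(self.names, self.f_min, self.f_max)
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MinMaxNormalizer":
        payload = json.loads(text)
        names = list(payload["features"])
        f_min = np.array([payload["features"][n]["min"] for n in names])
        f_max = np.array([payload["features"][n]["max"] for n in names])
        return cls(f_min=f_min, f_max=f_max, fitted_on=payload.get("fitted_on", ""), names=names)


def correct(normalized: np.ndarray, normalized_baseline_mean: np.ndarray) -> np.ndarray:
    """Baseline subtraction on normalised features; result lies in [-1, 1]."""
    return np.asarray(normalized, float) - np.asarray(normalized_baseline_mean, float)


def correct_trial(trial: TrialFeatures, normalizer: MinMaxNormalizer) -> np.ndarray:
    """Normalise a trial's windows and subtract its normalised baseline mean.

    Returns an (n_experimental, 48) matrix of corrected features.  Baseline
    windows only supply the per-trial mean; they are not returned.
    """
    base = np.stack([w.values for w in trial.baseline_windows])
    expe = np.stack([w.values for w in trial.experimental_windows])
    base_n = normalizer.transform(base)
    expe_n = normalizer.transform(expe)
    return correct(expe_n, base_n.mean(axis=0))
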