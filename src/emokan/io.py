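"""Adapters for the two public emotion-EEG distributions, plus fixture writers.

Both loaders select the four frontal channels (FP1, FP2, AF3, AF4) by name
from the montage, never by hard-coded position.  The fixture writers produce
files in exactly the same layout and exist so the adapters can be tested on
synthetic data; real downloads are license-gated and never required.
"""

from __future__ import annotations

import pickle
from pathlib import Path

import numpy as np
from scipy import io as sio
from scipy import signal

from .bands import CHANNELS
from .errors import MalformedTrialError
from .trial import EEGTrial

#: The preprocessed 32-channel (Geneva) order of the DEAP distribution.
DEAP_CHANNEL_ORDER = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7", "CP5", "CP1", "P3",
    "P7", "PO3", "O1", "Oz", "Pz", "Fp2", "AF4", "F4", "F8", "FC6", "FC2",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2", "Fz", "Cz",
)

#: The 62-channel order of the SEED recordings.
SEED_CHANNEL_ORDER = (
    "FP1", "FPZ", "FP2", "AF3", "AF4", "F7", "F5", "F3", "F1", "FZ", "F2",
    "F4", "F6", "F8", "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6",
    "FT8", "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8", "TP7",
    "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8", "P7", "P5", "P3",
    "P1", "PZ", "P2", "P4", "P6", "P8", "PO7", "PO5", "PO3", "POZ", "PO4",
    "PO6", "PO8", "CB1", "O1", "OZ", "O2", "CB2",
)

SEED_LABEL_NAMES = {-1: "negative", 0: "neutral", 1: "positive"}


def _indices(order, wanted=CHANNELS):
    upper = [name.upper() for name in order]
    try:
        return [upper.index(ch) for ch in wanted]
    except ValueError as exc:
        raise MalformedTrialError(f"montage is missing a required channel: {exc}") from exc


def deap_quadrant(valence: float, arousal: float, threshold: float = 5.0) -> str:
    """Joint valence-arousal quadrant; ratings must EXCEED the threshold for 'high'."""
    v = "H" if valence > threshold else "L"
    a = "H" if arousal > threshold else "L"
    return f"{v}V{a}A"


def load_deap_subject(path, task: str = "four_class", threshold: float = 5.0,
                      fs: float = 128.0) -> list[EEGTrial]:
    """Load one subject file of the preprocessed distribution (pickled dict
    with ``data`` (40, n_ch, n) and ``labels`` (40, 4) ratings)."""
    with open(path, "rb") as handle:
        payload = pickle.load(handle, encoding="latin1")
    try:
        data, ratings = payload["data"], payload["labels"]
    except (TypeError, KeyError) as exc:
        raise MalformedTrialError(f"{path}: expected a dict with 'data' and 'labels'") from exc
    data = np.asarray(data)
    ratings = np.asarray(ratings)
    if data.ndim != 3 or ratings.shape != (data.shape[0], 4):
        raise MalformedTrialError(f"{path}: unexpected array shapes {data.shape}, {ratings.shape}")
    idx = _indices(DEAP_CHANNEL_ORDER[: data.shape[1]])
    subject = Path(path).stem
    trials = []
    for t in range(data.shape[0]):
        valence, arousal = float(ratings[t, 0]), float(ratings[t, 1])
        if task == "four_class":
            label = deap_quadrant(valence, arousal, threshold)
        elif task == "valence":
            label = "high" if valence > threshold else "low"
        elif task == "arousal":
            label = "high" if arousal > threshold else "low"
        else:
            raise ValueError(f"unknown task {task!r}")
        trials.append(EEGTrial(
            samples=data[t, idx, :].T, fs=fs, label=label,
            trial_id=f"{subject}_t{t:02d}", subject_id=subject,
        ))
    return trials


def write_deap_fixture(path, data: np.ndarray, ratings: np.ndarray) -> None:
    """Write a subject file in the distribution's layout (inverse of the loader)."""
    with open(path, "wb") as handle:
        pickle.dump({"data": np.asarray(data), "labels": np.asarray(ratings)}, handle)


def load_seed_session(path, labels_path, fs: float = 200.0,
                      bandpass=(4.0, 45.0)) -> list[EEGTrial]:
    """Load one SEED session (.mat, one ``*_eeg<i>`` array per trial, 62 x n)
    with its label file; applies the 4-45 Hz band-pass on load."""
    if not Path(labels_path).exists():
        raise FileNotFoundError(f"SEED label file not found: {labels_path}")
    mat = sio.loadmat(path)
    labels = sio.loadmat(labels_path).get("label")
    if labels is None:
        raise MalformedTrialError(f"{labels_path}: missing 'label' array")
    labels = np.asarray(labels).ravel().astype(int)
    keys = sorted((k for k in mat if k.endswith(tuple(f"_eeg{i}" for i in range(1, 100)))),
                  key=lambda k: int(k.rsplit("_eeg", 1)[1]))
    if not keys:
        raise MalformedTrialError(f"{path}: no '*_eeg<i>' trial arrays found")
    if len(keys) != len(labels):
        raise MalformedTrialError(f"{path}: {len(keys)} trials but {len(labels)} labels")
    idx = _indices(SEED_CHANNEL_ORDER)
    sos = (signal.butter(4, list(bandpass), btype="bandpass", fs=fs, output="sos")
           if bandpass is not None else None)
    session = Path(path).stem
    trials = []
    for t, key in enumerate(keys):
        arr = np.asarray(mat[key])
        if arr.ndim != 2 or arr.shape[0] < max(idx) + 1:
            raise MalformedTrialError(f"{path}:{key}: expected (62, n) samples")
        picked = arr[idx, :].astype(float)
        samples = (signal.sosfiltfilt(sos, picked, axis=1) if sos is not None else picked).T
        trials.append(EEGTrial(
            samples=samples, fs=fs, label=SEED_LABEL_NAMES[int(labels[t])],
            trial_id=f"{session}_t{t:02d}", subject_id=session,
        ))
    return trials


def write_seed_fixture(path, labels_path, trials_data, labels,
                       prefix: str = "subject") -> None:
    """Write a session + label file in the SEED layout (inverse of the loader)."""
    mat = {f"{prefix}_eeg{i + 1}": np.asarray(arr) for i, arr in enumerate(trials_data)}
    sio.savemat(path, mat)
    sio.savemat(labels_path, {"label": np.asarray(labels).reshape(1, -1)})
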