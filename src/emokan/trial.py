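"""The trial container shared by the simulator, the dataset adapters and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bands import CHANNELS
from .errors import MalformedTrialError


@dataclass
class EEGTrial:
    """One stimulus presentation: a 3-s baseline followed by the experimental signal."""

    samples: np.ndarray  # (n_samples, 4) microvolts
    fs: float
    label: object
    trial_id: str = ""
    subject_id: str = ""
    baseline_seconds: float = 3.0
    channel_names: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[1] != len(self.channel_names):
            raise MalformedTrialError(
                f"trial {self.trial_id!r}: expected (n, {len(self.channel_names)}) samples"
            )
        if self.samples.shape[0] <= self.baseline_seconds * self.fs:
            raise MalformedTrialError(
                f"trial {self.trial_id!r} is not longer than its baseline"
            )

    @property
    def seconds(self) -> float:
        return self.samples.shape[0] / self.fs
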