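"""Synthetic 4-channel EEG emulating the trial structure of the public
emotion datasets: a 3-s class-neutral baseline followed by a 60-s
experimental segment, 1/f background noise and band-limited (4-45 Hz)
oscillations whose per-channel amplitudes encode the emotion class.

Class identity is carried by multiplicative band gains (features are
power-based), including inter-hemispheric gain asymmetries that drive the
EVI/ASI features; oscillation phases are randomised per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .bands import CHANNELS, DEFAULT_BANDS, Band
from .errors import ConfigError
from .trial import EEGTrial


@dataclass
class SynthConfig:
    fs: float = 128.0
    trial_seconds: float = 63.0
    baseline_seconds: float = 3.0
    classes: tuple = ("HVHA", "HVLA", "LVHA", "LVLA")
    #: label -> band name -> per-channel amplitude gains (FP1, FP2, AF3, AF4)
    band_gains: dict = field(default_factory=dict)
    #: baseline (class-neutral) oscillation amplitude per band, in uV std
    band_amplitudes: dict = field(
        default_factory=lambda: {"theta": 4.0, "alpha": 5.0, "beta": 4.0, "gamma": 3.0})
    noise_exponent: float = 1.0  # 1/f^exponent power slope of the background
    #: oscillation std / background std; < 1 because the aperiodic component
    #: carries most of the power in resting EEG
    snr: float = 0.5
    bands: tuple = DEFAULT_BANDS

    def __post_init__(self) -> None:
        if self.fs < 128:
            raise ConfigError("fs must be at least 128 Hz")
        for gains in self.band_gains.values():
            for g in gains.values():
                if np.any(np.asarray(g) <= 0):
                    raise ConfigError("band gains must be positive")


def default_four_class_config(effect: float = 3.0, **overrides) -> SynthConfig:
    """A strongly separable 4-class configuration.

    Two classes differ by opposite alpha-gain lateralisation, the other two
    by global beta / gamma power; ``effect`` is the dominant gain multiplier.
    """
    e = effect
    gains = overrides.pop("band_gains", {
        "HVHA": {"alpha": (e, 1.0, e, 1.0)},
        "HVLA": {"alpha": (1.0, e, 1.0, e)},
        "LVHA": {"beta": (e, e, e, e)},
        "LVLA": {"gamma": (e, e, e, e), "theta": (e, 1.0, e, 1.0)},
    })
    return SynthConfig(band_gains=gains, **overrides)


def _pink_noise(rng: np.random.Generator, n: int, fs: float, exponent: float,
                f_lo: float = 4.0, f_hi: float = 45.0) -> np.ndarray:
    """Unit-std 1/f^exponent (power) noise, band-limited to [f_lo, f_hi]."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    spectrum = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    amplitude = np.zeros(len(freqs))
    in_band = (freqs >= f_lo) & (freqs <= f_hi)
    amplitude[in_band] = freqs[in_band] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * amplitude, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _narrowband(rng: np.random.Generator, n: int, fs: float, band: Band) -> np.ndarray:
    """Unit-std narrow-band noise: white noise band-passed to the band."""
    sos = signal.butter(4, [band.f_low, band.f_high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n + 2 * int(fs)))[int(fs):int(fs) + n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _segment(rng: np.random.Generator, n: int, config: SynthConfig,
             gains: dict) -> np.ndarray:
    """One (n, 4) segment with the given per-band channel gains."""
    out = np.zeros((n, len(CHANNELS)))
    osc_std = np.array(
        [config.band_amplitudes.get(b.name, 0.0) for b in config.bands])
    # independent components add in power; noise std set by the SNR ratio
    noise_std = np.sqrt(np.sum(osc_std ** 2)) / max(config.snr, 1e-9)
    for ci in range(len(CHANNELS)):
        for b, amp in zip(config.bands, osc_std):
            gain = np.asarray(gains.get(b.name, np.ones(4)), dtype=float)[ci]
            out[:, ci] += amp * gain * _narrowband(rng, n, config.fs, b)
        out[:, ci] += noise_std * _pink_noise(rng, n, config.fs, config.noise_exponent)
    return out


def simulate_trial(class_label, config: SynthConfig, seed,
                   trial_id: str = "", subject_id: str = "") -> EEGTrial:
    """One trial: class-neutral baseline followed by class-gained signal.

    Deterministic given ``(class_label, config, seed)``.
    """
    if class_label not in config.classes:
        raise ConfigError(f"unknown class {class_label!r}; have {config.classes}")
    rng = np.random.default_rng(seed)
    n_base = int(round(config.baseline_seconds * config.fs))
    n_expe = int(round((config.trial_seconds - config.baseline_seconds) * config.fs))
    baseline = _segment(rng, n_base, config, gains={})
    experimental = _segment(rng, n_expe, config, gains=config.band_gains.get(class_label, {}))
    return EEGTrial(
        samples=np.vstack([baseline, experimental]), fs=config.fs, label=class_label,
        trial_id=trial_id or f"{class_label}-{seed}", subject_id=subject_id,
        baseline_seconds=config.baseline_seconds,
    )


def simulate_dataset(config: SynthConfig, n_trials_per_class: int, seed: int = 0,
                     n_subjects: int = 8) -> list[EEGTrial]:
    """A balanced dataset with distinct per-trial seeds and cycling subjects."""
    if n_trials_per_class < 1:
        raise ConfigError("n_trials_per_class must be positive")
    trials = []
    counter = 0
    for rep in range(n_trials_per_class):
        for label in config.classes:
            trial_seed = (int(seed) * 1_000_003 + counter * 7919 + 1) % (2 ** 31)
            trials.append(simulate_trial(
                label, config, trial_seed,
                trial_id=f"t{counter:04d}_{label}",
                subject_id=f"S{counter % n_subjects:02d}",
            ))
            counter += 1
    return trials
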