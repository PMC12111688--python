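"""Band-limited EEG features on the four frontal channels.

Four feature families are computed per 1-s window:

* band power (PSD) — the Welch spectral density integrated over the band,
* differential entropy (DE) — ``0.5*ln(2*pi*e*sigma^2)`` of the band-filtered
  signal under a Gaussian assumption,
* EVI — the log ratio of theta power between two channels (inter-hemispheric
  theta asymmetry),
* ASI — the normalised power difference ``(P1-P2)/(P1+P2)`` in the alpha,
  beta and gamma bands.

A window over the channels FP1, FP2, AF3, AF4 yields 48 features:
16 DE (4 bands x 4 channels), 16 PSD, and 16 spatial features
(4 theta-EVI + 12 ASI over 4 channel pairs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import BandRangeError, DegenerateSignalError

CHANNELS = ("FP1", "FP2", "AF3", "AF4")

#: Channel pairs used for the spatial (EVI / ASI) features, in canonical order.
PAIRS = (("FP1", "FP2"), ("AF3", "AF4"), ("FP1", "AF4"), ("AF3", "FP2"))


@dataclass(frozen=True)
class Band:
    """A frequency band ``[f_low, f_high]`` in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not 0.0 < self.f_low < self.f_high:
            raise BandRangeError(
                f"band {self.name!r}: need 0 < f_low < f_high, got "
                f"({self.f_low}, {self.f_high})"
            )


#: Default band edges; the source data is band-limited to 4-45 Hz.
DEFAULT_BANDS = (
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 13.0),
    Band("beta", 13.0, 30.0),
    Band("gamma", 30.0, 45.0),
)

THETA, ALPHA, BETA, GAMMA = DEFAULT_BANDS


@dataclass
class EEGWindow:
    """One fixed-length multichannel EEG segment (microvolts)."""

    samples: np.ndarray  # (n_samples, n_channels)
    fs: float
    channel_names: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (n_samples, n_channels)")
        if self.samples.shape[1] != len(self.channel_names):
            raise ValueError("channel_names must match the sample matrix width")

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; have {self.channel_names}") from None
        return self.samples[:, idx]


@dataclass
class FeatureWindow:
    """The 48 features of one window, in canonical order.

    Each block is band-major (theta, alpha, beta, gamma) and channel- or
    pair-minor.  The spatial block holds the 4 theta-EVI values first,
    then 12 ASI values for alpha/beta/gamma over the same 4 pairs.
    """

    de: np.ndarray  # (16,)
    psd: np.ndarray  # (16,)
    spatial: np.ndarray  # (16,)
    window_index: int = 0
    trial_id: str = ""
    is_baseline: bool = False
    label: object = None

    def __post_init__(self) -> None:
        for name in ("de", "psd", "spatial"):
            block = np.asarray(getattr(self, name), dtype=np.float64)
            if block.shape != (16,):
                raise ValueError(f"{name} block must have 16 entries")
            setattr(self, name, block)

    @property
    def values(self) -> np.ndarray:
        """All 48 features as one vector (de | psd | spatial)."""
        return np.concatenate([self.de, self.psd, self.spatial])


def feature_names(bands=DEFAULT_BANDS, channels=CHANNELS, pairs=PAIRS) -> list[str]:
    """Canonical names of the 48 features, matching ``FeatureWindow.values``."""
    names = [f"de_{b.name}_{ch}" for b in bands for ch in channels]
    names += [f"psd_{b.name}_{ch}" for b in bands for ch in channels]
    names += [f"evi_{bands[0].name}_{a}-{b}" for a, b in pairs]
    names += [f"asi_{band.name}_{a}-{b}" for band in bands[1:] for a, b in pairs]
    return names


def bandpass_filter(window: EEGWindow, band: Band, order: int = 4) -> EEGWindow:
    """Zero-phase Butterworth band-pass of every channel in the window."""
    nyq = window.fs / 2.0
    if band.f_high > nyq:
        raise BandRangeError(
            f"band {band.name!r} upper edge {band.f_high} Hz exceeds Nyquist {nyq} Hz"
        )
    sos = signal.butter(order, [band.f_low, band.f_high], btype="bandpass", fs=window.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, window.samples, axis=0)
    return EEGWindow(filtered, window.fs, window.channel_names)


def welch_psd(window: EEGWindow, channel: str, nperseg: int = 256):
    """Welch spectral density (Hann, 50% overlap) of one channel; (freqs, density)."""
    x = window.channel(channel)
    nper = min(len(x), nperseg)
    return signal.welch(x, fs=window.fs, window="hann", nperseg=nper, noverlap=nper // 2)


def welch_band_power(window: EEGWindow, channel: str, band: Band, nperseg: int = 256) -> float:
    """Band power (uV^2): the Welch density integrated over ``[f_low, f_high)``.

    Half-open bins make adjacent bands partition the spectrum without
    double-counting boundary bins.
    """
    freqs, density = welch_psd(window, channel, nperseg)
    df = freqs[1] - freqs[0]
    mask = (freqs >= band.f_low) & (freqs < band.f_high)
    return float(np.sum(density[mask]) * df)


def de_from_variance(variance: float) -> float:
    """Differential entropy (nats) of a Gaussian with the given variance."""
    if not variance > 0:
        raise DegenerateSignalError(f"variance must be positive, got {variance}")
    return 0.5 * math.log(2.0 * math.pi * math.e * variance)


def band_de(window: EEGWindow, channel: str, band: Band) -> float:
    """DE of the band-filtered channel: ``0.5*ln(2*pi*e*var)`` of the filtered samples."""
    filtered = bandpass_filter(window, band)
    return de_from_variance(float(np.var(filtered.channel(channel))))


def evi(theta_power_1: float, theta_power_2: float) -> float:
    """Log ratio of theta power between two channels; antisymmetric under swap."""
    if not (theta_power_1 > 0 and theta_power_2 > 0):
        raise DegenerateSignalError("EVI requires strictly positive theta powers")
    return math.log(theta_power_1 / theta_power_2)


def asi(p1: float, p2: float) -> float:
    """Normalised power difference ``(p1-p2)/(p1+p2)`` in [-1, 1]."""
    if p1 < 0 or p2 < 0:
        raise DegenerateSignalError("ASI requires nonnegative powers")
    total = p1 + p2
    if total == 0:
        raise DegenerateSignalError("ASI undefined for two zero powers")
    return (p1 - p2) / total


@dataclass
class FeatureExtractor:
    """Computes the 48-feature vector of a window.

    Band powers are computed once per (channel, band) and reused by the PSD
    and spatial features; DE is computed from the band-filtered variance.
    """

    bands: tuple[Band, ...] = DEFAULT_BANDS
    pairs: tuple[tuple[str, str], ...] = PAIRS
    nperseg: int = 256
    channels: tuple[str, ...] = field(default=CHANNELS)

    def __call__(self, window: EEGWindow, **meta) -> FeatureWindow:
        return self.extract(window, **meta)

    def extract(self, window: EEGWindow, **meta) -> FeatureWindow:
        power = {}
        for ch in self.channels:
            freqs, density = welch_psd(window, ch, self.nperseg)
            df = freqs[1] - freqs[0]
            for band in self.bands:
                mask = (freqs >= band.f_low) & (freqs < band.f_high)
                power[band.name, ch] = float(np.sum(density[mask]) * df)

        de = []
        for band in self.bands:
            filtered = bandpass_filter(window, band)
            for ch in self.channels:
                de.append(de_from_variance(float(np.var(filtered.channel(ch)))))

        psd = [power[band.name, ch] for band in self.bands for ch in self.channels]

        theta = self.bands[0]
        spatial = [evi(power[theta.name, a], power[theta.name, b]) for a, b in self.pairs]
        for band in self.bands[1:]:
            spatial += [asi(power[band.name, a], power[band.name, b]) for a, b in self.pairs]

        return FeatureWindow(np.array(de), np.array(psd), np.array(spatial), **meta)


def extract_features(window: EEGWindow, pairs=PAIRS, bands=DEFAULT_BANDS, **meta) -> FeatureWindow:
    """Extract the canonical 48 features (16 DE, 16 PSD, 4 EVI + 12 ASI) of a window."""
    return FeatureExtractor(bands=bands, pairs=pairs)(window, **meta)
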