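"""Exception hierarchy shared across the package."""


class EmokanError(Exception):
    """Base class for package-specific errors."""


class BandRangeError(EmokanError, ValueError):
    """A frequency band is invalid for the given sampling rate (e.g. above Nyquist)."""


class DegenerateSignalError(EmokanError, ValueError):
    """A window has zero variance / zero band power, so log-based features are undefined."""


class MalformedTrialError(EmokanError, ValueError):
    """A trial is too short or structurally inconsistent (e.g. shorter than its baseline)."""


class ConfigError(EmokanError, ValueError):
    """An invalid model, spline-grid or training configuration."""


class TrainingDivergedError(EmokanError, RuntimeError):
    """The loss became non-finite during optimisation."""
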