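"""Exception hierarchy shared by all pipeline stages."""


class WearagreeError(Exception):
    """Base class for every error raised by this package."""


class ConfigurationError(WearagreeError, ValueError):
    """Invalid configuration value (non-positive rate, cutoff >= Nyquist, ...)."""


class SchemaError(WearagreeError, ValueError):
    """Structural mismatch: wrong channel labels, row lengths, unordered times."""


class RangeError(WearagreeError, ValueError):
    """A time or index falls outside the span of the data it addresses."""


class DetectionError(WearagreeError, RuntimeError):
    """No synchronization event found above threshold (missing tap)."""


class ProcessingError(WearagreeError, RuntimeError):
    """A signal-processing stage cannot run (signal too short, window too long)."""


class AlignmentError(WearagreeError, RuntimeError):
    """Rigid-body alignment failed (too few matched frames, degenerate data)."""


class InsufficientDataError(WearagreeError, ValueError):
    """Fewer observations than the statistic requires."""


class DegenerateDataError(WearagreeError, ValueError):
    """Statistic undefined on the data (zero variance, rank-deficient mean)."""
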