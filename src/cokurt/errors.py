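"""Exception hierarchy for cokurt."""


class CokurtError(Exception):
    """Base class for all package errors."""


class DataError(CokurtError):
    """Non-finite or otherwise invalid numeric input."""


class DegenerateFeatureError(DataError):
    """A feature column has zero variance and cannot be standardized."""


class DegenerateSpectrumError(DataError):
    """All singular values are zero; no kurtosis signal to normalize."""


class DistributionError(DataError):
    """Inputs are not valid discrete probability distributions."""


class WindowTooShortError(CokurtError):
    """A sample is shorter than the requested sub-block size."""


class OrderingError(CokurtError):
    """Stream records arrived out of time order."""


class ConfigurationError(CokurtError):
    """Invalid configuration (ranges, thresholds, window specs...)."""


class InsufficientHistoryError(CokurtError):
    """Not enough history to compute an adaptive bound."""

    def __init__(self, message: str, count: int = 0):
        super().__init__(message)
        self.count = count


class TrainingDivergedError(CokurtError):
    """A non-finite loss was encountered during adversarial training."""

    def __init__(self, message: str, epoch: int = -1):
        super().__init__(message)
        self.epoch = epoch
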