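"""Exception hierarchy for ptrkit."""


class PtrKitError(Exception):
    """Base class for all ptrkit errors."""


class ConfigError(PtrKitError):
    """Invalid configuration value."""


class FormatError(PtrKitError):
    """Malformed input file."""


class NormalizationError(PtrKitError):
    """Normalization cannot proceed (e.g. zero library size)."""


class PairingError(PtrKitError):
    """mRNA/protein tables cannot be paired."""


class UndefinedCorrelationError(PtrKitError):
    """Correlation is undefined (too few points or zero variance)."""


class FitError(PtrKitError):
    """Regression cannot be fitted."""


class MatchingInfeasibleError(PtrKitError):
    """Expression-matched sampling is infeasible for at least one bin."""

    def __init__(self, message, bins=None):
        super().__init__(message)
        self.bins = bins or []


class SamplingError(PtrKitError):
    """Randomized-null sampling cannot proceed."""


class UnknownConditionError(PtrKitError, KeyError):
    """Condition identifier not present in a dataset."""
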