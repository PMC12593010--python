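"""Exception hierarchy for the EMG-FPCA pipeline.

All pipeline-specific failures derive from :class:`EmgFpcaError` so callers
can distinguish domain errors from programming errors.
"""


class EmgFpcaError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(EmgFpcaError):
    """A required column is missing or a column map is inconsistent."""


class IntegrityError(EmgFpcaError):
    """Input violates a structural constraint (e.g. mixed sampling rates)."""


class ConfigurationError(EmgFpcaError):
    """A configuration value is invalid for the data at hand."""


class DataError(EmgFpcaError):
    """Signal content is unusable (NaNs, cycle too short, too few curves)."""


class NormalizationError(EmgFpcaError):
    """Amplitude normalization is undefined (e.g. all-zero trial set)."""


class UndefinedEffectError(EmgFpcaError):
    """An effect size is undefined (zero variance in the denominator)."""
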