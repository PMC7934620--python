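"""Exception hierarchy for trial-data validation and index computation."""


class TrialDataError(ValueError):
    """Base class for all data/configuration problems raised by this package."""


class SchemaError(TrialDataError):
    """A required column is missing or a column mapping is invalid."""


class DesignError(TrialDataError):
    """The trial layout violates the two-treatment split-plot contract."""


class UndefinedRateError(TrialDataError):
    """Percent reduction is undefined (high-fertility mean is zero)."""


class StressOrientationError(TrialDataError):
    """Stress intensity SI = 1 - Ylf/Yhf is not positive, so SFSI is undefined."""


class ConfigurationError(TrialDataError):
    """A run/simulation configuration is inconsistent (e.g. unknown check)."""
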