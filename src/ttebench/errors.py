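"""Exception types shared across the pipeline."""


class TTEBenchError(Exception):
    """Base class for all package errors."""


class ConfigError(TTEBenchError):
    """A configuration value is invalid; the message names the field."""


class DataIntegrityError(TTEBenchError):
    """Input tables violate a structural assumption (e.g. overlapping enrollment spans)."""


class EmptyArmError(TTEBenchError):
    """A cohort arm is empty after eligibility filtering."""


class DegenerateArmError(TTEBenchError):
    """An arm has too few members for a between-arm summary."""


class SeparationError(TTEBenchError):
    """The propensity model is perfectly separated; covariate pruning is required."""
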