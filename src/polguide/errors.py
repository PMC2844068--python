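"""Exception hierarchy for polguide."""


class PolguideError(Exception):
    """Base class for all polguide errors."""


class FormatError(PolguideError, ValueError):
    """Input file does not conform to the expected schema."""


class ValidationError(PolguideError, ValueError):
    """Data violate a domain invariant (e.g. non-monotone times)."""


class UndefinedStatisticError(PolguideError, ValueError):
    """A statistic is undefined for the given input (e.g. zero resultant)."""


class FitError(PolguideError, RuntimeError):
    """A model fit could not be carried out or did not converge."""


class ConfigError(PolguideError, ValueError):
    """Invalid configuration for a generator or simulation."""
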