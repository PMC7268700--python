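"""Exception hierarchy for hospexp."""


class HospexpError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HospexpError, ValueError):
    """A configuration file or object violates the schema or an invariant."""


class NormalizationError(ConfigurationError):
    """A categorical distribution (shares) does not sum to one."""


class AssignmentError(HospexpError, LookupError):
    """A patient could not be matched to an institution of the chosen type."""
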