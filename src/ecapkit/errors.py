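"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: validation errors (2), data/bounds errors
(3), numerical failures (4).
"""


class EcapkitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EcapkitError, ValueError):
    """An object violates a structural invariant; message names the field."""


class ConfigurationError(EcapkitError, ValueError):
    """A configuration value is missing, unknown, or inconsistent."""


class BoundsError(EcapkitError, IndexError):
    """A requested time window or index falls outside the available data."""


class NumericalError(EcapkitError, RuntimeError):
    """An iterative numerical procedure failed to converge."""
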