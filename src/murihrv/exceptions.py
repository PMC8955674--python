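"""Exception hierarchy shared across the package."""


class MuriHRVError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MuriHRVError, ValueError):
    """An invalid parameter or configuration object."""


class FormatError(MuriHRVError, ValueError):
    """A malformed input file."""


class ValidationError(MuriHRVError, ValueError):
    """Data violating a structural invariant (e.g. negative interval)."""


class InsufficientDataError(MuriHRVError, ValueError):
    """Not enough samples/beats/intervals for the requested operation."""
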