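"""Exception hierarchy.

Exit-code mapping used by the CLI: validation/configuration problems exit
with 1, degenerate estimates (e.g. zero total emergence, which would send a
log-transformed rate to infinity) exit with 2.
"""


class HostparError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(HostparError, ValueError):
    """Invalid input data, design levels, or record invariants."""

    exit_code = 1


class DataError(ValidationError):
    """Data internally inconsistent (e.g. wasps recorded without attacks)."""


class ConfigurationError(HostparError, LookupError):
    """A required parameter key is missing from a parameter set."""

    exit_code = 1


class DegenerateEstimateError(HostparError):
    """A closed-form estimate is undefined (infinite or 0/0) for these data."""

    exit_code = 2
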