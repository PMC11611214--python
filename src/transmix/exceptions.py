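"""Exception taxonomy.

Validation errors signal malformed input; an undefined estimate (a group
that emitted no transmissions in the analysis window) is a normal outcome
of small outbreaks and is carried as a status, only raised when nothing
sensible can be returned at all.
"""


class TransmixError(Exception):
    """Base class for all package errors."""


class ValidationError(TransmixError, ValueError):
    """Structurally invalid input (bad sizes, unknown group, broken tree)."""


class UndefinedEstimateError(TransmixError):
    """No transmissions emitted: the within-group proportion has no estimate."""
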