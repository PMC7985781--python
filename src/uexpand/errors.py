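"""Exception hierarchy.

Argument problems (bad orders, malformed schedules, missing samples) raise
:class:`ArgumentError`; requests that are well-formed but exceed a documented
capability of the implementation (combinatorial order caps) raise
:class:`CapabilityError`.  The CLI maps them to exit codes 2 and 3.
"""


class UExpandError(Exception):
    """Base class for all package errors."""


class ArgumentError(UExpandError, ValueError):
    """An argument violates a documented precondition."""


class CapabilityError(UExpandError):
    """The request exceeds a documented capability limit of the package."""
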