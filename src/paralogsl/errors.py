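"""Exception hierarchy shared across the package."""


class ParalogSLError(Exception):
    """Base class for all package errors."""


class InputError(ParalogSLError):
    """Raised for unreadable, empty, or missing input files."""


class ValidationError(ParalogSLError):
    """Raised when an input parses but violates a contract
    (duplicate identifiers, out-of-range values, degenerate panels, ...)."""
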