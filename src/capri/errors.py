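"""Exception hierarchy.

``ValidationError`` maps to CLI exit code 2, ``EstimationError`` to 3.
"""


class CapriError(Exception):
    """Base class for all package errors."""


class ValidationError(CapriError):
    """Invalid input data, configuration, or profile/design structure."""


class EstimationError(CapriError):
    """Model fitting failed (rank deficiency, degenerate data, ...)."""
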