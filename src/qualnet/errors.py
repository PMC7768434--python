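"""Exception hierarchy shared across the package.

Validation errors signal bad input data (CLI exit code 2); capacity errors
signal a runtime guard tripping, e.g. the maximal-biclique output cap
(CLI exit code 3).
"""


class QualnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(QualnetError):
    """A file is structurally malformed (missing column, ragged row, bad cell)."""


class ValidationError(QualnetError):
    """Structurally readable input violates a data-model invariant."""


class CapacityError(QualnetError):
    """A configured complexity guard was exceeded."""
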