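"""Exception hierarchy.

Validation failures (bad user input) map to CLI exit code 2; everything
else propagates as ordinary errors.
"""


class NBDeconvError(Exception):
    """Base class for all package errors."""


class ValidationError(NBDeconvError):
    """Malformed or inconsistent input data."""


class ConfigurationError(NBDeconvError):
    """A mode or parameter combination that cannot be honoured."""


class DegenerateInputError(NBDeconvError):
    """Structurally valid input on which the requested computation is undefined."""


class BundleError(NBDeconvError):
    """Reference-bundle I/O problem (missing table, schema mismatch)."""
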