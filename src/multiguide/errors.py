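"""Exception hierarchy.

``FormatError`` covers malformed input files (exit code 2 at the CLI);
``ConfigurationError`` covers invalid parameters or impossible requests
(exit code 1).
"""


class MultiguideError(Exception):
    """Base class for package-specific errors."""


class FormatError(MultiguideError):
    """An input file violates its format contract."""


class ConfigurationError(MultiguideError):
    """A parameter set is invalid or a request is infeasible."""
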