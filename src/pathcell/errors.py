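"""Exception hierarchy.

``UsageError`` maps to CLI exit code 2 (bad invocation), ``DataError`` to
exit code 1 (well-formed invocation, bad data).
"""


class PathcellError(Exception):
    """Base class for all package errors."""


class DataError(PathcellError):
    """Invalid or inconsistent data (parse failures, empty results, ...)."""


class ParseError(DataError):
    """A file could not be parsed; message names the offending line."""


class UsageError(PathcellError):
    """Invalid parameters or invocation."""
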