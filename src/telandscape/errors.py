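"""Exception hierarchy shared across the package.

All exceptions derive from :class:`TELandscapeError` so callers can catch
package failures with a single ``except`` clause while the CLI maps them to
exit codes.
"""


class TELandscapeError(Exception):
    """Base class for all package-specific errors."""


class RepeatParseError(TELandscapeError):
    """A tabular or sequence input could not be parsed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class DomainError(TELandscapeError, ValueError):
    """Inputs are syntactically fine but scientifically invalid
    (e.g. inverted percentages, empty community, zero genome size)."""


class UsageError(TELandscapeError, ValueError):
    """A parameter value outside its documented range (unknown level token,
    non-positive bin width, empty threshold list)."""


class StructureError(TELandscapeError):
    """An element model is geometrically inconsistent (internal region
    engulfing every terminal repeat)."""


class UndefinedRatioError(TELandscapeError, ZeroDivisionError):
    """A depth ratio is undefined because the internal region received no
    aligned bases; the contig is skipped in aggregates."""
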