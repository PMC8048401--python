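"""Exception hierarchy shared across the package."""


class HomeRangeError(Exception):
    """Base class for all package errors."""


class SchemaError(HomeRangeError):
    """Input table is missing required columns or has the wrong dialect."""


class TimestampParseError(HomeRangeError):
    """A timestamp could not be parsed; carries the offending row index."""

    def __init__(self, row, value):
        self.row = row
        self.value = value
        super().__init__(f"unparseable timestamp at row {row}: {value!r}")


class CRSError(HomeRangeError):
    """Missing, unknown, or geographic coordinate reference system."""


class DomainError(HomeRangeError):
    """A parameter is outside its mathematical domain (e.g. level > 1)."""


class DegenerateGeometryError(HomeRangeError):
    """Too few / collinear points to build the requested polygon."""


class UnsupportedOperationError(HomeRangeError):
    """Operation not defined for this estimator class (e.g. UD of an MCP)."""


class ConvergenceError(HomeRangeError):
    """Optimizer failed to converge; carries best-so-far parameters."""

    def __init__(self, message, best=None):
        self.best = best
        super().__init__(message)
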