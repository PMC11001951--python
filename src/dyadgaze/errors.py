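"""Exception hierarchy shared across the package."""


class DyadGazeError(Exception):
    """Base class for all package-specific errors."""


class DegenerateGeometryError(DyadGazeError, ValueError):
    """Raised when landmarks or rays do not define the requested geometry
    (collinear landmarks, zero-length directions, coincident points)."""


class ConfigurationError(DyadGazeError, ValueError):
    """Raised for invalid analysis or simulation configuration
    (negative AOI radius, infeasible overlap, bad truncation range)."""


class FormatError(DyadGazeError, ValueError):
    """Raised when an on-disk artefact violates its documented schema.
    Messages always name the offending location (row / column / field)."""


class IntegrityError(DyadGazeError, ValueError):
    """Raised when inputs are schema-valid but mutually inconsistent
    (stream does not cover a trial, empty trial window, no valid frames)."""


class DegenerateTestError(DyadGazeError, ValueError):
    """Raised when a statistical test is undefined on its input
    (zero-variance differences, non-positive degrees of freedom)."""
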