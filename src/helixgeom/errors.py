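"""Exception hierarchy shared across the package."""


class HelixGeomError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HelixGeomError):
    """A structure file could not be parsed (no ATOM records, bad fields...)."""


class InsufficientTraceError(HelixGeomError):
    """Too few C-alpha atoms to define a helix trace."""


class DegenerateGeometryError(HelixGeomError):
    """A geometric quantity is undefined at the requested point
    (vanishing tangent, vanishing curvature, rank-deficient point set)."""


class DomainError(HelixGeomError):
    """Evaluation requested outside the parameter domain of a fitted curve."""
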