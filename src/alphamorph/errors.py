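"""Exception hierarchy shared across the package."""


class AlphamorphError(Exception):
    """Base class for all package-specific errors."""


class MeshFormatError(AlphamorphError):
    """A mesh file could not be read or parsed."""


class MeshValidationError(AlphamorphError):
    """A mesh violates a structural invariant (open edges, bad winding, ...)."""


class GeometryError(AlphamorphError):
    """A geometric computation received degenerate input."""


class SizeError(AlphamorphError, ValueError):
    """An input is too small (or a requested count too large) for the operation."""


class DomainError(AlphamorphError, ValueError):
    """A numeric parameter is outside its valid domain."""


class LabelMappingError(AlphamorphError):
    """Species labels in the data and tree tips do not match."""


class DegenerateVariableError(AlphamorphError):
    """A variable has zero variance and cannot be standardized."""


class CollinearityError(AlphamorphError):
    """A regression design matrix is rank deficient."""


class DesignError(AlphamorphError):
    """A statistical design is invalid (e.g. a single group in an ANOVA)."""


class RankError(AlphamorphError):
    """More response dimensions than the design can support."""


class StateError(AlphamorphError):
    """An operation was called before its prerequisites were computed."""
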