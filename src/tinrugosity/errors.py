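"""Exception types raised by tinrugosity."""


class TinRugosityError(Exception):
    """Base class for all package-specific errors."""


class MeshFormatError(TinRugosityError):
    """A mesh file could not be parsed as a pure-triangle surface."""


class DegenerateGeometryError(TinRugosityError):
    """Geometry is degenerate (zero-area triangle, collinear points, ...)."""


class EmptyChainError(TinRugosityError):
    """No mesh vertices fall within the chain selection threshold."""


class TerrainSpecError(TinRugosityError):
    """A synthetic-terrain specification violates its invariants."""
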