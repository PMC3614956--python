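"""Exception hierarchy shared by all aquaflux stages."""


class AquafluxError(Exception):
    """Base class for all errors raised by aquaflux."""


class ParseError(AquafluxError):
    """A structure or trajectory file could not be parsed."""


class EmptyInputError(AquafluxError):
    """An input contained no usable records (no atoms, no frames, no waters)."""


class StructureError(AquafluxError):
    """Inputs are individually valid but structurally inconsistent."""


class ParameterError(AquafluxError):
    """A parameter value is outside its allowed domain."""


class SelectionError(AquafluxError):
    """An atom selection is empty or ambiguous where exactly one atom is required."""


class UndefinedGeometryError(AquafluxError):
    """A geometric quantity (e.g. a dihedral with a collinear axis) is undefined."""


class InsufficientDataError(AquafluxError):
    """Not enough frames/windows/events to compute the requested estimate."""


class ConfigError(AquafluxError):
    """A run configuration is missing mandatory fields or is inconsistent."""
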