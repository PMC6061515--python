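"""Exception hierarchy for altchip."""


class AltChipError(ValueError):
    """Base class for all altchip input/state errors."""


class InvalidParameterError(AltChipError):
    """A chip or search parameter is outside its legal range."""


class LengthMismatchError(AltChipError):
    """A fragment or prefix has the wrong length for the requested pattern."""


class PatternError(AltChipError):
    """A string violates the alternating-chip probe pattern it claims to follow."""


class InvalidSpectrumError(AltChipError):
    """A spectrum mixes element lengths or otherwise contradicts its chip parameter."""


class InvalidInstanceError(AltChipError):
    """Target length, prefix and chip parameter do not form a solvable instance."""


class UnknownVertexError(AltChipError):
    """A vertex queried from the overlap graph is not part of it."""


class SpectrumParseError(AltChipError):
    """A spectrum file could not be parsed; the message names the offending line."""
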