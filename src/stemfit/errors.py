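"""Exception hierarchy."""


class StemfitError(Exception):
    """Base class for all package errors."""


class DomainError(StemfitError, ValueError):
    """A parameter or argument is outside its mathematical domain."""


class GridError(StemfitError, ValueError):
    """A frequency grid violates its construction invariants."""


class SpectrumFormatError(StemfitError, ValueError):
    """A spectrum file cannot be parsed or fails validation."""
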