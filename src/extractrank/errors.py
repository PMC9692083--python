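"""Exception types shared across the package."""


class ExtractRankError(ValueError):
    """Base class for all package errors."""


class FormatError(ExtractRankError):
    """An input file does not conform to its expected dialect."""


class ValidationError(ExtractRankError):
    """An input violates a data-model invariant."""


class ParameterError(ExtractRankError):
    """A threshold or option is outside its admissible range."""
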