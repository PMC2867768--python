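"""Exception hierarchy shared across the package."""


class AlimaskError(Exception):
    """Base class for all package-specific errors."""


class AlignmentShapeError(AlimaskError):
    """Rows of unequal length, or a mask/alignment length mismatch."""


class AlphabetError(AlimaskError):
    """A character outside the declared alphabet, its ambiguity codes and '-'."""


class InputError(AlimaskError):
    """Structurally invalid input (too few sequences, empty distribution, ...)."""


class ConfigurationError(AlimaskError):
    """An unsupported option value (unknown matrix, window wider than the alignment, ...)."""
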