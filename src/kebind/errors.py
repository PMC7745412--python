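"""Exception hierarchy shared across the package."""


class KebindError(Exception):
    """Base class for all package-specific errors."""


class ParseError(KebindError):
    """Malformed input file (FASTA, dot-bracket, shape file)."""


class AlphabetError(KebindError):
    """A character outside the expected alphabet was encountered."""


class AlignmentError(KebindError):
    """Sequences and per-sequence annotations do not line up."""


class ConfigError(KebindError):
    """Invalid model, training, or generator configuration."""


class DatasetError(KebindError):
    """A dataset violates a precondition (empty, single-class, too small)."""
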