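"""Exception types shared across the pipeline stages."""


class CircamotifError(Exception):
    """Base class for all package errors."""


class FastaParseError(CircamotifError, ValueError):
    """Malformed FASTA input (empty file, illegal character, ...)."""


class MotifParseError(CircamotifError, ValueError):
    """Malformed PFM / motif-family input."""


class RangeError(CircamotifError, ValueError):
    """A coordinate or window falls outside the available sequence."""


class DegenerateMatrixError(CircamotifError, ValueError):
    """A PWM whose min and max attainable scores coincide."""


class GenerationError(CircamotifError, RuntimeError):
    """Synthetic sequence generation failed (e.g. purge did not converge)."""
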