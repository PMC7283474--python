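"""Exception hierarchy.

Exit-code mapping used by the CLI: usage errors -> 2, data errors -> 3,
numerical errors -> 4.
"""


class TcrPmhcError(Exception):
    """Base class for all package errors."""


class DataError(TcrPmhcError):
    """Problems with input data (parsing, annotation, pairing)."""


class ParseError(DataError):
    """Unreadable or malformed structure file."""


class FormatError(DataError):
    """Unknown or unsupported file format."""


class AnnotationError(DataError):
    """Incomplete or ambiguous chain-role / loop-range annotation."""


class CysDetectionError(DataError):
    """No qualifying conserved disulfide pair found."""


class PairingError(DataError):
    """Residue/atom correspondence could not be established."""


class NumericalError(TcrPmhcError):
    """Degenerate geometry or failed numerical procedure."""


class GeometryError(NumericalError):
    """Degenerate geometric input (collinear, zero-length, ...)."""


class FrameError(GeometryError):
    """Reference frame could not be constructed."""


class RankingError(DataError):
    """Empty or invalid reference table."""


class RadiiError(DataError):
    """Atom radius could not be resolved."""


class ScUndefinedError(NumericalError):
    """No interface dots; shape complementarity is undefined."""


class FitError(NumericalError):
    """Nonlinear fit failed or is unidentifiable."""


class IdentifiabilityError(FitError):
    """Data cannot determine the requested parameters."""


class GenerationError(TcrPmhcError):
    """Synthetic-structure generation was infeasible."""
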