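"""Exception hierarchy for the PDC codec.

All package errors derive from :class:`PdcError` so callers can catch one
base class at the CLI boundary.
"""


class PdcError(Exception):
    """Base class for all PDC errors."""


class UnsupportedResidueError(PdcError):
    """Residue type outside the 20 standard amino acids."""


class IncompleteResidueError(PdcError):
    """A residue is missing atoms, or carries atoms its type does not define."""


class UnsupportedInputError(PdcError):
    """Input file violates the single-chain, ATOM-only contract
    (multiple chains, HETATM records, altlocs, insertion codes, ...)."""


class FormatError(PdcError):
    """Unparseable file or unrecognised PDC magic/version."""


class CorruptionError(FormatError):
    """A PDC payload is truncated or internally inconsistent."""


class RangeError(PdcError):
    """A coordinate or temperature factor exceeds its fixed-point range."""


class DeltaOverflowError(RangeError):
    """A coordinate/B-factor difference does not fit its target integer width."""


class DegenerateGeometryError(PdcError):
    """Coincident or collinear points where a dihedral frame is required."""


class ValidationError(PdcError):
    """Inconsistent in-memory data (mismatched lengths, unordered indices, ...)."""
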