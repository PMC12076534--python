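"""Shared exception types, one per documented failure class."""


class PdbmendError(Exception):
    """Base class for all package errors."""


class EmptyStructureError(PdbmendError):
    """No parsable ATOM/HETATM record in the input."""


class CoordinateOverflowError(PdbmendError):
    """A coordinate does not fit the fixed-width PDB columns."""


class AlphaTraceError(PdbmendError):
    """Chain provides only CA atoms; the backbone sequence cannot be perceived."""


class SequenceMismatchError(PdbmendError):
    """SEQRES and the observed ATOM sequence disagree beyond tolerance."""


class ChainTooLargeError(PdbmendError):
    """Chain exceeds the configured heavy-atom processing limit."""


class BoxTooLargeError(PdbmendError):
    """Solvated box would exceed the configured total atom budget."""


class GapRepairError(PdbmendError):
    """All candidate orientations failed for at least one gap."""


class TopologyError(PdbmendError):
    """Atoms present that the assigned residue variant does not define."""
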