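"""Exception hierarchy.

Input-format problems (unreadable PDB, inconsistent models) and contract
violations (incompatible maps, degenerate selections) are kept distinct so the
command line can map them onto separate exit codes.
"""


class FlexmapError(Exception):
    """Base class for all package errors."""


class PDBParseError(FlexmapError):
    """A PDB file could not be parsed; the message cites the offending line."""


class PDBFormatError(FlexmapError):
    """A structure cannot be represented in fixed-column PDB format."""


class TopologyMismatchError(PDBParseError):
    """Models of a multi-model PDB do not share an identical atom list."""


class SelectionError(FlexmapError):
    """A selection resolved to an unusable (typically empty) atom set."""


class ContractError(FlexmapError):
    """Operation preconditions violated (incompatible inputs, bad windows)."""


class FitError(ContractError):
    """Rigid-body superposition is undefined (too few or degenerate points)."""


class ConstantSeriesError(ContractError):
    """Correlation requested between series of which one is constant."""


class SpecValidationError(FlexmapError):
    """A synthetic-ensemble specification is internally inconsistent."""
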