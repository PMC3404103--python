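"""Exception hierarchy shared across the package."""


class SFCollapseError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(SFCollapseError):
    """A PDB record could not be parsed; the message names the line number."""


class TopologyError(SFCollapseError):
    """Models of a multi-model file (or trajectory frames) disagree on atoms."""


class SelectionError(SFCollapseError):
    """A selection expression is malformed; the message names the position."""


class FitError(SFCollapseError):
    """A least-squares fit (superposition or curve fit) is degenerate or failed."""


class DegenerateCoordinateError(SFCollapseError):
    """The two reference structures coincide after superposition (span ~ 0)."""


class MappingError(SFCollapseError):
    """Atoms of a selection cannot be resolved in another structure/topology."""


class LookupAtomError(SFCollapseError):
    """A requested atom (chain/residue/name) does not exist in the model."""


class WindowError(SFCollapseError):
    """A requested analysis window is empty or outside the data range."""


class EnsembleError(SFCollapseError):
    """Fewer runs than required for an ensemble statistic (need >= 2)."""


class CriteriaError(SFCollapseError):
    """Hydrogen-bond criteria are inconsistent with the structure's contents."""


class RadiusTableError(SFCollapseError):
    """An element has no van der Waals radius in the configured table."""


class ManifestError(SFCollapseError):
    """A scan manifest is invalid or references missing files."""


class RatioError(SFCollapseError):
    """A ratio is undefined (zero denominator)."""
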