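"""Exception hierarchy for macpep."""


class MacpepError(Exception):
    """Base class for all macpep errors."""


class GeometryError(MacpepError):
    """Degenerate geometry (e.g. collinear points for a dihedral)."""


class InvalidTorsionError(MacpepError):
    """A torsion was requested that the residue does not define."""


class InsufficientPointsError(MacpepError):
    """Too few points for a superposition."""


class AtomMappingError(MacpepError):
    """Atom selections of two poses do not match."""


class PDBParseError(MacpepError):
    """Unreadable or garbled PDB input."""


class UnknownResidueError(MacpepError):
    """Residue name outside the supported set (strict mode)."""


class ScoringError(MacpepError):
    """Missing atoms or radii during scoring."""


class ConfigurationError(MacpepError):
    """Invalid configuration (weights, palettes, schedules...)."""


class AnchorClashError(MacpepError):
    """The fixed anchor overlaps the target."""


class NoPlacementError(MacpepError):
    """No clash-free rotamer placement exists."""


class ResidueLookupError(MacpepError):
    """Requested chain/residue not present in a structure."""


class UndefinedInterfaceError(MacpepError):
    """Shape complementarity requested for bodies that do not touch."""


class RankingError(MacpepError):
    """A design record lacks the metrics needed for ranking."""


class InsufficientSamplesError(MacpepError):
    """Too few landscape points for a funnel verdict."""


class FixtureGenerationError(MacpepError):
    """A synthetic fixture could not be generated for the requested spec."""


class ParameterError(MacpepError):
    """Out-of-range user parameter."""
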