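"""Exception hierarchy. Each pipeline stage raises a subclass so failures
carry a stage-tagged message."""


class MCLigandError(Exception):
    """Base class for all package errors."""


class SelectorError(MCLigandError):
    """Residue selector did not match exactly one residue."""


class LigandInputError(MCLigandError):
    """The selected residue cannot be used as a ligand (no heavy atoms,
    disconnected components, bad occupancies...)."""


class BondAssignmentError(MCLigandError):
    """SMILES template could not be mapped onto the ligand coordinates."""


class MapError(MCLigandError):
    """Density map or structure-factor input could not be read or used."""


class SamplingError(MCLigandError):
    """Conformer generation failed or under-delivered."""


class SolverError(MCLigandError):
    """Occupancy optimization failed."""


class MetricError(MCLigandError):
    """A validation metric is undefined for the given inputs."""
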