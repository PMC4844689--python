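"""Exception hierarchy shared by all horizonte modules."""


class HorizonteError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(HorizonteError):
    """Malformed input file (FASTA, Newick, TSV, config)."""


class NewickError(FormatError):
    """Newick string could not be parsed, or violates the tree contract
    (polytomy under the 'reject' policy, duplicate leaf names, ...)."""


class AlignmentError(HorizonteError):
    """Rows of unequal length, empty alignment, or coordinate mismatch."""


class DivergenceError(HorizonteError):
    """Distance could not be computed."""


class NoComparableSitesError(DivergenceError):
    """Pairwise deletion removed every site of the comparison."""


class SaturationError(DivergenceError):
    """Substitution saturation: the K2P log argument is non-positive."""


class ReconciliationError(HorizonteError):
    """Invalid reconciliation input (unmapped leaf, non-binary tree)."""


class BiogeographyError(HorizonteError):
    """Invalid area assignment (unknown area, empty set, over the cap)."""


class AnnotationError(HorizonteError):
    """Invalid ORF coordinates or alignment for copy annotation."""


class SimulationError(HorizonteError):
    """Simulation parameters are invalid or infeasible."""


class ConfigError(HorizonteError):
    """Pipeline configuration is invalid or references missing inputs."""
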