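"""Exception hierarchy shared across the pipeline."""


class MscError(Exception):
    """Base class for all mscscreen errors."""


class StructureFormatError(MscError):
    """A coordinate or alignment file could not be parsed."""


class EmptySelectionError(MscError):
    """A chain or atom filter matched nothing."""


class StructuralMismatchError(MscError):
    """Trajectory frames disagree on atom count or ordering."""


class AlignmentLengthError(MscError):
    """An alignment has rows of unequal length."""


class ResidueAlignmentError(MscError):
    """Two per-residue profiles cover different residue-id sets."""


class DegenerateSuperpositionError(MscError):
    """Fewer than 3 atoms, or a collinear atom set, in a superposition mask."""


class InsufficientFramesError(MscError):
    """Too few post-equilibration frames for a fluctuation estimate."""


class ClashError(MscError):
    """Receptor/ligand atoms overlap inside the Lennard-Jones core."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        super().__init__(f"steric clash between {len(self.pairs)} atom pair(s): "
                         f"{self.pairs[:5]}")


class NonTerminationError(MscError):
    """A pull run exceeded its hard step cap without reaching the stop distance."""


class MappingError(MscError):
    """Alignment columns cannot be mapped onto structure residues."""


class FitError(MscError):
    """A nonlinear fit failed to converge."""


class NoDecayError(MscError):
    """Inactivation data show no decay (fitted rate constant <= 0)."""


class CalibrationError(MscError):
    """Standard-curve input is rank deficient or insufficient."""


class GenerationError(MscError):
    """A synthetic-data generator could not satisfy its constraints."""


class ConfigError(MscError):
    """A screen configuration is incomplete or contradictory."""


class StageError(MscError):
    """A pipeline stage failed; wraps the underlying error with the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
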