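"""Exception hierarchy for hbscreen."""


class HBScreenError(Exception):
    """Base class for all hbscreen errors."""


class CodeParseError(HBScreenError, ValueError):
    """A shorthand end-group code does not match the grammar."""


class CapacityError(CodeParseError):
    """More hydrogen-bond sites than the supported maximum of three."""


class AlignmentError(HBScreenError, ValueError):
    """Invalid alignment request (empty pattern, out-of-range contacts...)."""


class GeometryError(HBScreenError, ValueError):
    """A pose geometry cannot be constructed from the given monomers."""


class AnnotationError(GeometryError):
    """A monomer geometry lacks a required site annotation."""


class UndefinedQuantityError(HBScreenError, ValueError):
    """A derived energy was requested from a record lacking its inputs."""


class EnergyTableError(HBScreenError, ValueError):
    """Malformed or inconsistent external energy table."""


class NoPlanarPoseError(HBScreenError, ValueError):
    """Every candidate pose was rejected by the planarity predicate."""

    def __init__(self, message, rejected=()):
        super().__init__(message)
        self.rejected = list(rejected)


class MissingPairError(HBScreenError, ValueError):
    """A roster pair has no energy record."""

    def __init__(self, message, pairs=()):
        super().__init__(message)
        self.pairs = list(pairs)


class UndefinedCorrelationError(HBScreenError, ValueError):
    """Pearson r is undefined (zero variance in one of the variables)."""


class InfeasiblePlantError(HBScreenError, ValueError):
    """A requested planted alphabet cannot be realised in the matrix."""
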