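"""Exception hierarchy."""


class BoolscanError(Exception):
    """Base class for all package-specific errors."""


class GranularityError(BoolscanError):
    """A variable's range exceeds the Boolean range [0, 1]."""


class UnsupportedRuleError(BoolscanError):
    """A target function uses a construct outside the supported grammar."""


class DanglingReferenceError(BoolscanError):
    """A rule references a node that does not exist in the model."""


class ModelLookupError(BoolscanError):
    """A requested node name is not present in the model."""


class AmbiguousPhenotypeError(BoolscanError):
    """A node name matches both a cell-specific suffix and the signal suffix."""


class ConflictError(BoolscanError):
    """Contradictory duplicate entries (edges, genes, observations)."""


class IncompleteAssignmentError(BoolscanError):
    """An input node was left without a value."""


class AssignmentError(BoolscanError):
    """A fixed-input key is not an input node of the model."""


class NonterminationError(BoolscanError):
    """Simulation exhausted its step budget before revisiting a state."""


class ResumeError(BoolscanError):
    """Checkpoint does not match the model/scan being resumed."""


class EmptyComparisonError(BoolscanError):
    """No observation key resolves to a model node; a score is undefined."""


class GenerationError(BoolscanError):
    """Random-fixture constraints are infeasible."""


class ScanGuardError(BoolscanError):
    """Free-input count exceeds the configured combination guard."""
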