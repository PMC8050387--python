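"""Exception hierarchy for the neurite-outgrowth quantification pipeline."""


class NeuriteQuantError(Exception):
    """Base class for all package errors."""


class InputError(NeuriteQuantError):
    """Missing files, dimension mismatches between co-registered inputs, NaNs."""


class FormatError(NeuriteQuantError):
    """Unreadable or inconsistent image containers (page shapes, bit depth)."""


class ParameterError(NeuriteQuantError):
    """Invalid parameter value (non-positive radius, empty scale list, ...)."""


class StatisticsError(NeuriteQuantError):
    """Degenerate statistical input: too few observations or zero variance."""


class GenerationError(NeuriteQuantError):
    """Synthetic-field generation could not satisfy a placement constraint."""


class AssignmentError(NeuriteQuantError):
    """Skeleton components cannot be assigned to cells (e.g. zero nuclei)."""


class ContractViolationError(NeuriteQuantError):
    """An internal invariant was violated (e.g. non-unit-width skeleton)."""
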