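"""Exception and warning types shared across the package."""


class LatticeForgeError(Exception):
    """Base class for all package errors."""


class ParameterError(LatticeForgeError, ValueError):
    """A parameter value violates its documented constraint."""


class DomainError(LatticeForgeError, ValueError):
    """An operation was applied to an input outside its domain (e.g. empty mask)."""


class GridMismatchError(LatticeForgeError, ValueError):
    """Two rasters that must share a grid do not."""


class StructureError(LatticeForgeError, ValueError):
    """A structure-set containment relation is violated."""


class FormatError(LatticeForgeError, ValueError):
    """A file is malformed or carries unsupported geometry/values."""


class GuidelineWarning(UserWarning):
    """A plan-quality guideline (not a hard constraint) is violated."""
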