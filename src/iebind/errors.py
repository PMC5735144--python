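"""Exception hierarchy shared across the package."""


class IEBindError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IEBindError, ValueError):
    """A file could not be parsed into the expected dialect."""


class ValidationError(IEBindError, ValueError):
    """A parsed or constructed object violates a type invariant."""


class EmptyInputError(IEBindError, ValueError):
    """An operation received zero frames / zero samples."""


class GeometryError(IEBindError, ValueError):
    """Degenerate geometry (coincident atoms, zero-length vectors)."""


class SchemeError(IEBindError, ValueError):
    """Inconsistent single-/triple-trajectory bookkeeping."""


class CompletenessError(IEBindError, ValueError):
    """A required free-energy component or species table is missing."""
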