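"""Exception hierarchy shared across the package."""


class TractMorphError(Exception):
    """Base class for all package errors."""


class ValidationError(TractMorphError, ValueError):
    """A configuration or input value violates a documented contract."""


class FormatError(TractMorphError, ValueError):
    """A file could not be parsed; the message carries line/offset context."""


class OutOfDomainError(TractMorphError, ValueError):
    """A point lies outside the domain of the lattice it was embedded in."""


class FitError(TractMorphError, RuntimeError):
    """The deformation fit could not be solved."""
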