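"""Exception hierarchy shared across the package."""


class PhylothermError(Exception):
    """Base class for all package-specific errors."""


class NewickParseError(PhylothermError):
    """Malformed Newick input; carries the character offset when known."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)


class TreeValidationError(PhylothermError):
    """A parsed tree violates a structural invariant (e.g. duplicate tips)."""


class TraitTableError(PhylothermError):
    """Malformed trait table; carries the offending line number when known."""


class MissingTraitError(PhylothermError):
    """A tip required by an analysis has no trait value."""


class NotUltrametricError(PhylothermError):
    """An operation requiring an ultrametric (time-calibrated) tree got one
    with unequal root-to-tip distances."""


class ParameterDomainError(PhylothermError):
    """A model parameter is outside its admissible domain."""


class NumericalSupportError(PhylothermError):
    """A density inversion has no usable numerical support (all components
    degenerate)."""


class MonophylyError(PhylothermError):
    """A tip set expected to be monophyletic is not; names the intruders."""


class ConfigError(PhylothermError):
    """Invalid pipeline or CLI configuration."""
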