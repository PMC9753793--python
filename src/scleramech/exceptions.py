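"""Exception hierarchy shared across the package."""


class ScleramechError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ScleramechError, ValueError):
    """A material, geometry, or protocol parameter violates its invariants."""


class InvalidInputError(ScleramechError, ValueError):
    """A data input (trace, table, image) violates its contract."""


class ConvergenceError(ScleramechError, RuntimeError):
    """An iterative routine failed to bracket or converge."""


class SeriesConvergenceError(ConvergenceError):
    """The eigenfunction series did not converge within the truncation cap."""

    def __init__(self, message: str, terms_used: int):
        super().__init__(message)
        self.terms_used = terms_used


class StabilityError(ScleramechError, RuntimeError):
    """A numerical scheme was run outside its stability envelope."""


class InsufficientRelaxationError(InvalidInputError):
    """A stress-relaxation trace never reached its equilibrium plateau."""


class MissingPairError(InvalidInputError):
    """An interocular difference was requested for an animal missing one eye."""

    def __init__(self, animals):
        self.animals = list(animals)
        super().__init__(f"missing paired-eye data for animals: {self.animals}")


class SegmentationError(InvalidInputError):
    """OCT interface positions are not monotone front-to-back."""


class EstimabilityError(ScleramechError, ValueError):
    """A requested model contrast is not estimable from the fitted model."""


class NestingError(ScleramechError, ValueError):
    """Likelihood-ratio test requested for non-nested models."""


class DependencyError(ScleramechError, RuntimeError):
    """A pipeline stage is missing outputs of an upstream stage."""
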