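"""Exception hierarchy.

All package-specific failures derive from :class:`SigmanetError` so callers
(and the CLI) can distinguish configuration problems from runtime failures.
"""


class SigmanetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SigmanetError):
    """Invalid parameter values, incompatible shapes, or bad run configs."""


class InvalidParameterError(ConfigurationError):
    """A scalar parameter is outside its valid range."""


class AlignmentError(ConfigurationError):
    """Sample tables that must be aligned (genotypes vs. locations) are not."""


class ExtinctionError(SigmanetError):
    """The simulated population died out before the requested generation."""


class InsufficientIndividualsError(SigmanetError):
    """A sample of n individuals was requested from a smaller population."""


class InsufficientSNPsError(SigmanetError):
    """Fewer segregating sites are available than requested."""


class EmptyInputError(SigmanetError):
    """An input file or store contained no usable records."""


class UnsupportedPloidyError(SigmanetError):
    """VCF samples are not diploid."""


class StoreIntegrityError(SigmanetError):
    """A dataset store file is corrupt or truncated."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message if offset is None else f"{message} (at byte offset {offset})")
        self.offset = offset


class StoreVersionError(SigmanetError):
    """A dataset store was written by an incompatible format version."""


class UndefinedStatisticError(SigmanetError):
    """A genetic statistic is undefined for the given input (e.g. monomorphic)."""


class SingularFitError(SigmanetError):
    """A regression design matrix is singular (e.g. all distances equal)."""


class DegenerateTrainingSetError(SigmanetError):
    """Training targets have zero variance; normalization is impossible."""


class DivergenceError(SigmanetError):
    """Training produced a non-finite loss."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message if step is None else f"{message} (step {step})")
        self.step = step
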