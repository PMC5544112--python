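"""Exception hierarchy.

Every error raised on a user-facing code path derives from :class:`HaprapError`
so the CLI can catch one type and exit nonzero with chunk context.
"""


class HaprapError(Exception):
    """Base class for all package errors."""


class InputError(HaprapError):
    """Malformed or empty input file."""


class PhaseError(InputError):
    """Unphased genotype in a panel that must be phased."""


class MissingDataError(InputError):
    """Missing genotype call; the panel must be complete (no imputation)."""


class UnsupportedRecordError(InputError):
    """Record outside the supported dialect (e.g. multi-allelic site)."""


class MissingSnpError(HaprapError):
    """Summary-statistic SNP absent from the reference panel."""


class AlleleMismatchError(HaprapError):
    """Allele pair in the summary statistics matches neither panel orientation."""


class StrandAmbiguityError(HaprapError):
    """Palindromic (A/T or C/G) SNP whose frequencies conflict beyond tolerance."""


class MonomorphicSnpError(HaprapError):
    """A SNP column carries a single allele in the panel."""


class EmptyRegionError(HaprapError):
    """Zero SNPs where at least one is required."""


class DimensionError(HaprapError):
    """Inconsistent vector/matrix dimensions."""


class NonConvergenceError(HaprapError):
    """Iteration cap reached before the residual criterion was met.

    Carries the residual trajectory for diagnosis.
    """

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory


class FeasibilityError(HaprapError):
    """Requested LD targets violate the constraints implied by the allele frequencies."""


class PanelDegeneracyError(HaprapError):
    """Sampled reference panel persistently monomorphic (tiny panel, rare allele)."""


class SingularDesignError(HaprapError):
    """Rank-deficient design matrix in a regression."""


class ConditioningError(HaprapError):
    """LD correlation matrix too ill-conditioned to invert reliably."""


class UnstableRegionError(HaprapError):
    """Too many bootstrap replicates failed to converge."""


class OrderingError(InputError):
    """SNPs not sorted by position where position order is required."""
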