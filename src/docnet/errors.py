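"""Exception and warning types shared across the pipeline."""


class DocnetError(Exception):
    """Base class for all pipeline errors."""


class InvalidPartitionError(DocnetError, ValueError):
    """Parcellation does not define a usable multi-network partition."""


class GenerationError(DocnetError, RuntimeError):
    """Synthetic data generation failed (e.g. covariance not repairable)."""


class EmptyCohortError(DocnetError, ValueError):
    """A cohort with zero subjects was requested."""


class InsufficientSamplesError(DocnetError, ValueError):
    """Too few timepoints for the requested operation."""


class InvalidBandError(DocnetError, ValueError):
    """Band-pass corner frequencies outside (0, Nyquist)."""


class CollinearityError(DocnetError, ValueError):
    """Confound design matrix is rank deficient."""


class DegenerateNodeError(DocnetError, ValueError):
    """One or more nodal series have zero variance."""


class InvalidStepError(DocnetError, ValueError):
    """Non-positive step for a density grid."""


class InvalidDensityError(DocnetError, ValueError):
    """Connection density outside (0, 1]."""


class UndefinedMetricError(DocnetError, ValueError):
    """Graph metric undefined for this input (e.g. no edges)."""


class UndefinedSigmaError(DocnetError, ValueError):
    """Small-worldness undefined (zero null means)."""


class OutOfRangeDistanceError(DocnetError, ValueError):
    """Inter-node distance outside the supported 0-180 mm range."""


class ParseError(DocnetError, ValueError):
    """Malformed on-disk artifact; message names the offending line."""


class ConfigError(DocnetError, ValueError):
    """Invalid pipeline configuration."""


class EmptyGraphWarning(UserWarning):
    """A density cut retained zero edges."""


class EmptyAdmissibleWarning(UserWarning):
    """No density satisfied the admissibility criteria."""


class RewiringStallWarning(UserWarning):
    """Degree-preserving rewiring accepted no (or very few) swaps."""


class BinSkippedWarning(UserWarning):
    """A distance bin was skipped in the group comparison."""


class UnstableResolutionWarning(UserWarning):
    """Permutation count too low for a stable p-value."""
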