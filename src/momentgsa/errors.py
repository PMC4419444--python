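"""Exception hierarchy shared across the package."""


class MomentGSAError(Exception):
    """Base class for all package-specific errors."""


class DegenerateGeneError(MomentGSAError):
    """A gene row is constant (zero variance) where scaling requires otherwise."""


class DegeneratePhenotypeError(MomentGSAError):
    """The phenotype vector is constant, so no permutation test is possible."""


class ShapeError(MomentGSAError):
    """Dimension mismatch between expression matrix and phenotype."""


class WeightSignError(MomentGSAError):
    """Negative gene weight supplied where the quadratic statistic requires w >= 0."""


class InsufficientSamplesError(MomentGSAError):
    """Too few samples for the requested moment (fourth moments need n >= 4)."""


class DegenerateStatisticError(MomentGSAError):
    """The statistic takes at most two distinct values under permutation."""


class GMTParseError(MomentGSAError):
    """Malformed line in a GMT gene set collection file."""
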