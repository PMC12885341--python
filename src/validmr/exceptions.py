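"""Exception types shared across the package."""


class ValidMRError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ValidMRError, ValueError):
    """A simulation or run configuration violates its invariants."""


class DimensionError(ValidMRError, ValueError):
    """Mismatched shapes between a config and a data container."""


class EmptyIntersectionError(ValidMRError, ValueError):
    """Two GWAS tables (or a table and a panel) share no SNPs."""


class UnknownSNPError(ValidMRError, KeyError):
    """A requested SNP id is absent from the genotype panel."""


class UnknownColumnError(ValidMRError, KeyError):
    """A requested phenotype/covariate column does not exist."""


class DegenerateScoreError(ValidMRError, ValueError):
    """A polygenic score has zero variance and cannot be standardized."""


class DegenerateInstrumentError(ValidMRError, ValueError):
    """Every cell of an instrument grid is degenerate."""


class DegenerateInputError(ValidMRError, ValueError):
    """An analysis input has zero variance (or residual variance)."""


class SingularityError(ValidMRError, ValueError):
    """Predictors are (near-)collinear."""


class InsufficientDataError(ValidMRError, ValueError):
    """Too few complete cases for the requested model."""


class InstrumentValidationError(ValidMRError, RuntimeError):
    """Stage-1 instrument validation failed; causal test refused."""


class ComparisonError(ValidMRError, ValueError):
    """A group comparison received fewer than two groups."""
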