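"""Exception hierarchy shared across the pipeline."""


class CodepError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CodepError):
    """Malformed input: out-of-range values, inconsistent axes, bad specs."""


class DegenerateInputError(CodepError):
    """A vector is constant (or collinear) where variation is required."""


class InsufficientDataError(CodepError):
    """Too few complete observations to compute the requested statistic."""


class ConfigError(CodepError):
    """Invalid configuration value (e.g. too few permutations)."""


class AnnotationError(CodepError):
    """A drug lacks the required on-target annotation."""


class CollinearityError(CodepError):
    """Two regressors are (near-)collinear; carries both identifiers."""

    def __init__(self, message, gene_a=None, gene_b=None):
        super().__init__(message)
        self.gene_a = gene_a
        self.gene_b = gene_b


class EmptyScreenError(CodepError):
    """Every drug in a discovery run was skipped; carries per-drug reasons."""

    def __init__(self, message, skip_log=None):
        super().__init__(message)
        self.skip_log = dict(skip_log or {})


class MappingError(CodepError):
    """A drug-analog mapping names a drug absent from the cohort."""


class GeneNotFoundError(CodepError):
    """A requested gene is missing from an expression matrix."""


class QuantileError(CodepError):
    """Ties are so heavy that an expression quartile is empty."""


class GroupError(CodepError):
    """A survival group contains no subjects."""


class NoEventsError(CodepError):
    """No events observed; the requested test is undefined."""


class ConvergenceError(CodepError):
    """Iterative fit failed to converge within the iteration budget."""


class SeparationError(CodepError):
    """Monotone partial likelihood (complete separation) in a Cox fit."""


class HorizonError(CodepError):
    """A time-dependent-AUC horizon lies beyond the observed follow-up."""


class DegenerateSplitWarning(UserWarning):
    """Median split could not separate groups (all scores tied)."""
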