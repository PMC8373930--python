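"""Exception hierarchy for foldstab."""


class FoldstabError(Exception):
    """Base class for all foldstab errors."""


class InvalidConditionError(FoldstabError, ValueError):
    """A measurement condition is physically invalid (e.g. T <= 0 K)."""


class InvalidParameterError(FoldstabError, ValueError):
    """A thermodynamic or design parameter violates its invariants."""


class NoTransitionError(FoldstabError, RuntimeError):
    """No unfolding transition detectable (flat derivative / no root in bracket)."""


class DegenerateBaselineError(FoldstabError, ValueError):
    """Native and unfolded baselines coincide; the transition is unidentifiable."""


class DegenerateFitError(FoldstabError, RuntimeError):
    """Singular Jacobian or otherwise unidentifiable global fit."""


class CovarianceUnavailableError(FoldstabError, RuntimeError):
    """A derived-quantity error was requested but the fit has no covariance."""


class IncompatibleRecordsError(FoldstabError, ValueError):
    """Stability records from different sources/reference temperatures combined."""


class InsufficientOverlapError(FoldstabError, ValueError):
    """Fewer than the minimum number of matched variants for a comparison."""


class EmptyInputError(FoldstabError, ValueError):
    """An aggregate operation received no values."""


class DesignError(FoldstabError, ValueError):
    """A synthetic experiment design violates its invariants."""


class VariantLookupError(FoldstabError, KeyError):
    """Requested variant label is not in the packaged reference table."""


class DataParseError(FoldstabError, ValueError):
    """A dataset file could not be parsed; message carries line numbers."""
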