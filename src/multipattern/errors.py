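"""Exception hierarchy for the multipattern pipeline."""


class MultipatternError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MultipatternError):
    """Invalid generator or run configuration (names the offending field)."""


class CohortFormatError(MultipatternError):
    """Malformed cohort CSV input (missing column, bad code, unknown id)."""


class InconsistencyError(MultipatternError):
    """Internal bookkeeping violated (negative counts, status conflicts)."""


class AtcFormatError(MultipatternError):
    """ATC code too short to carry a level-4 (5-character) prefix."""


class EmptyWaveError(MultipatternError):
    """No patients remain in a wave after attrition."""


class ClusteringError(MultipatternError):
    """Invalid clustering request (k out of range, length mismatch)."""


class NoValidPartitionError(ClusteringError):
    """No candidate k produced a partition where every cluster has an
    essential disease."""

    def __init__(self, failures: dict):
        self.failures = dict(failures)
        detail = "; ".join(f"k={k}: {msg}" for k, msg in self.failures.items())
        super().__init__(f"no valid partition among candidates ({detail})")


class UndefinedPrevalenceRatioError(MultipatternError):
    """Prevalence ratio requested with zero expected prevalence."""


class SeparationError(MultipatternError):
    """Perfect separation in a regression model."""


class ConvergenceError(MultipatternError):
    """Iterative fit failed to converge within the iteration budget."""
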