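"""Exception hierarchy for the O/E pipeline."""


class OEFishError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(OEFishError, ValueError):
    """Invalid configuration (bad counts, proportions, missing thresholds...)."""


class SchemaError(OEFishError, KeyError):
    """A required column is absent from a table."""


class DataError(OEFishError, ValueError):
    """A value in a table is unusable (non-numeric where a number is required)."""


class ConsistencyError(OEFishError, ValueError):
    """Cross-table references disagree (e.g. a survey points at an unknown reach)."""


class UnfittableSpeciesError(OEFishError, ValueError):
    """The outcome vector cannot support a presence/absence model (single class)."""


class ConvergenceError(OEFishError, RuntimeError):
    """Learning-rate halving exhausted without reaching the minimum tree count."""


class DegenerateTargetError(OEFishError, ValueError):
    """A regression target with no variance cannot be modelled."""


class ThresholdError(OEFishError, ValueError):
    """Kappa threshold selection is undefined (single-class labels)."""
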