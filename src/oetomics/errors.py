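"""Exception hierarchy for the pipeline."""


class OetError(Exception):
    """Base class for all package errors."""


class InputError(OetError):
    """Malformed or inconsistent input data (unknown stage, duplicate gene ids, ...)."""


class ConfigError(OetError):
    """Invalid configuration (class proportions, missing cluster mapping, ...)."""


class CorrectionError(OetError):
    """Batch correction cannot be computed or applied."""


class AnalysisError(OetError):
    """A downstream analysis has no valid input (empty eligible set, too few genes, ...)."""


class FitError(OetError):
    """Kinetic model fitting failed (no observations, non-finite objective)."""
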