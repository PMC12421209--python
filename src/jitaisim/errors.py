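"""Exception types shared across the pipeline."""


class JitaisimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(JitaisimError, ValueError):
    """A configuration value violates a documented constraint."""


class InsufficientDataError(JitaisimError, ValueError):
    """Not enough observations to compute the requested quantity."""


class DegenerateVarianceError(JitaisimError, ValueError):
    """Both groups have zero variance; the contrast is not estimable."""


class ConsistencyError(JitaisimError, ValueError):
    """Cross-referenced inputs (records, decisions) do not line up."""


class PhaseError(JitaisimError, ValueError):
    """An operation was requested outside the study phase it belongs to."""
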