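"""Exception hierarchy for evpem."""


class EvpemError(Exception):
    """Base class for all package errors."""


class InvalidInputError(EvpemError, ValueError):
    """A value violates a documented precondition or type invariant."""


class ConfigurationError(EvpemError):
    """A model/coefficient configuration is incomplete or inconsistent."""


class FittingError(EvpemError):
    """Least-squares fitting failed (e.g. rank-deficient design)."""


class UndefinedMetricError(EvpemError):
    """A goodness-of-fit metric is undefined for the given vectors."""


class IntegrityError(EvpemError):
    """A bundled fixture failed validation on load."""
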