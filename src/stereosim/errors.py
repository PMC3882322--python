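"""Exception hierarchy shared across the package."""


class StereosimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(StereosimError):
    """A parameter or configuration file is invalid."""


class AnalysisError(StereosimError):
    """A statistical operation was asked to run on unusable input."""


class MeasurementError(StereosimError):
    """A virtual measurement could not be completed (e.g. unbounded profile)."""


class ConsistencyError(StereosimError):
    """An internal invariant was violated (indicates a bug, not bad input)."""
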