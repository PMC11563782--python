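"""Exception hierarchy shared across the package."""


class HyphabendError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HyphabendError, ValueError):
    """Invalid construction parameters (non-positive geometry, bad config)."""


class DomainError(HyphabendError, ValueError):
    """Arguments outside the physical/mathematical domain of an operation."""


class ConfigurationMismatchError(HyphabendError, ValueError):
    """An operation was applied to the wrong channel configuration."""


class ConvergenceError(HyphabendError, RuntimeError):
    """An iterative solve failed to converge."""


class FitError(HyphabendError, RuntimeError):
    """A least-squares fit had no usable data."""


class NetworkError(HyphabendError, ValueError):
    """A fluidic network is disconnected or otherwise unsolvable."""
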