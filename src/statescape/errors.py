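"""Exception types shared across the package."""


class StatescapeError(Exception):
    """Base class for all package-specific errors."""


class DomainError(StatescapeError, ValueError):
    """Input outside the mathematical domain of an operation."""


class ContractError(StatescapeError, ValueError):
    """A documented precondition (unit norm, matching frame, ...) is violated."""


class ConfigError(StatescapeError, ValueError):
    """Invalid run configuration or fixture specification."""
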