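"""Exception types shared across the package."""


class LtfAssayError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(LtfAssayError, ValueError):
    """A parameter violates a documented precondition."""


class SchemaError(LtfAssayError, ValueError):
    """An input table or config file does not match the documented schema."""


class InsufficientTissueError(LtfAssayError):
    """Not enough pooled tissue area to form the requested number of pools.

    Carries ``achievable_pools`` so callers can retry with a feasible request.
    """

    def __init__(self, message: str, achievable_pools: int):
        super().__init__(message)
        self.achievable_pools = achievable_pools


class UndefinedStatisticError(LtfAssayError):
    """A statistic (CV, slope, ...) is undefined for the given data.

    Raised instead of silently returning zero so downstream stages must
    handle the condition explicitly.
    """
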