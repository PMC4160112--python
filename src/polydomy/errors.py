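"""Exception hierarchy used across the package."""


class PolydomyError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PolydomyError):
    """A delimited-text input does not match the documented schema."""


class IntegrityError(PolydomyError):
    """Cross-references between tables are inconsistent (dangling ids,
    duplicate edges, missing foraging profiles)."""


class DomainError(PolydomyError, ValueError):
    """An argument lies outside the mathematical domain of an estimator."""


class GenerationError(PolydomyError):
    """A synthetic-colony configuration cannot be satisfied."""


class UndefinedStatisticError(PolydomyError):
    """A test statistic is undefined on the given data (e.g. zero variance).

    Inside a permutation test this triggers resampling of the permutation;
    on observed data it propagates to the caller.
    """
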