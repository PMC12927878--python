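"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: configuration problems -> 2, data problems
(including invalid inputs) -> 3, degenerate statistical models -> 4.
"""


class LoticError(Exception):
    """Base class for all package errors."""


class InvalidInputError(LoticError, ValueError):
    """An argument violates a documented pre-condition."""


class OrderingError(InvalidInputError):
    """Sites are not strictly ordered downstream (strictly decreasing rkm)."""


class ConfigError(LoticError):
    """A run configuration is inconsistent or infeasible."""


class DataError(LoticError):
    """Input data cannot be used as required."""


class EmptyResultError(DataError):
    """An operation produced or would operate on an empty result set."""


class MappingError(DataError):
    """Sample-to-site mapping is incomplete or ambiguous."""


class DegenerateModelError(LoticError):
    """A statistical model cannot be fitted (constant predictor, etc.)."""


class RankDeficiencyError(DegenerateModelError):
    """Design matrix is rank deficient (collinear predictors)."""


EXIT_CODES = {
    ConfigError: 2,
    DataError: 3,
    InvalidInputError: 3,
    DegenerateModelError: 4,
}


def exit_code_for(exc: BaseException) -> int:
    for cls, code in EXIT_CODES.items():
        if isinstance(exc, cls):
            return code
    return 1
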