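"""Exception hierarchy shared across the package."""


class ConfauditError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ConfauditError, ValueError):
    """A configuration field is missing, out of range, or inconsistent."""


class DataError(ConfauditError, ValueError):
    """Input data violate a contract (missing values, misaligned rows, ...)."""


class SingularConfoundsError(DataError):
    """The confound matrix is rank deficient under a linear-family remover."""

    def __init__(self, offending_columns):
        self.offending_columns = list(offending_columns)
        super().__init__(
            "confound matrix is rank deficient; linearly dependent columns: "
            f"{self.offending_columns}"
        )


class UndefinedScoreError(ConfauditError, ValueError):
    """R^2 is undefined (constant true values)."""


class FoldError(ConfauditError, RuntimeError):
    """A cross-validation stage failed; carries the fold index."""

    def __init__(self, fold, stage, original):
        self.fold = fold
        self.stage = stage
        self.original = original
        super().__init__(f"fold {fold}: stage '{stage}' failed: {original}")


class BudgetError(ConfauditError, RuntimeError):
    """A permutation run would exceed the configured model-fit budget."""
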