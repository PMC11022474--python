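"""Exception hierarchy for dietscore.

All package errors derive from :class:`DietscoreError` so callers can catch
one base class at the CLI boundary.
"""


class DietscoreError(Exception):
    """Base class for all dietscore errors."""


class ConfigError(DietscoreError):
    """A configuration file or table violates its schema or invariants."""


class DataError(DietscoreError):
    """Input data are malformed (bad rows, missing columns, bad values)."""

    def __init__(self, message: str, row_errors: list[str] | None = None):
        super().__init__(message)
        self.row_errors = row_errors or []


class UnmappedItemError(DataError):
    """Food items present in the records are absent from the group map."""

    def __init__(self, item_ids):
        ids = sorted(str(i) for i in set(item_ids))
        super().__init__(
            f"{len(ids)} item id(s) missing from the group map: {', '.join(ids[:20])}"
            + (" ..." if len(ids) > 20 else "")
        )
        self.item_ids = ids


class DegenerateInputError(DietscoreError):
    """Input is constant/degenerate where variation is required."""


class CollinearityError(DietscoreError):
    """Model design matrix is rank deficient."""


class ConvergenceError(DietscoreError):
    """Iterative fit failed to converge (e.g. separation in logistic fit)."""
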