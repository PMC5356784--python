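"""Exception hierarchy for the ddcnv pipeline."""


class DdcnvError(Exception):
    """Base class for all ddcnv errors."""


class SaturationError(DdcnvError):
    """All droplets positive: lambda (and the concentration) is inestimable."""


class DegenerateWellError(DdcnvError):
    """A two-sided confidence interval is undefined (0 or all droplets positive)."""


class InvalidMergeError(DdcnvError):
    """Wells from different samples or channels cannot be pooled."""


class UndefinedRatioError(DdcnvError):
    """The reference concentration is zero; the target/reference ratio is undefined."""


class SchemaError(DdcnvError):
    """An input table does not conform to the documented CSV schema."""


class DegenerateTableError(DdcnvError):
    """A contingency table has an empty margin; no association test is possible."""


class JoinError(DdcnvError):
    """Sample identifiers do not match between two tables that must be joined."""
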