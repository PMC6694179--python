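"""Exception hierarchy for rootbranch."""


class RootBranchError(Exception):
    """Base class for all package-specific errors."""


class ParameterDomainError(RootBranchError, ValueError):
    """A branching parameter lies outside its admissible domain."""


class InputSizeError(RootBranchError, ValueError):
    """An input is too small for the requested operation."""


class SampleSizeError(RootBranchError, ValueError):
    """Too few observations for a reliable estimate."""


class EstimationFailureError(RootBranchError, RuntimeError):
    """Indicator estimation produced a degenerate result (e.g. non-positive mode)."""


class CalibrationQualityError(RootBranchError, RuntimeError):
    """A marginal indicator-parameter relation is unusable for inversion."""


class BinningError(RootBranchError, RuntimeError):
    """Too few usable bins for the chi-square comparison."""


class SplitError(RootBranchError, ValueError):
    """The diameter split produced an empty sub-population."""


class SchemaError(RootBranchError, ValueError):
    """An input table does not match the expected CSV schema."""


class LabelingError(RootBranchError, ValueError):
    """Duplicate or invalid sample labels in a panel."""
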