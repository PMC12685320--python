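"""Exception hierarchy for triagedca."""


class TriageDcaError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TriageDcaError):
    """An input table does not have the expected columns."""


class ValidationError(TriageDcaError, ValueError):
    """A value violates a documented invariant (e.g. proportion outside [0, 1])."""


class InconsistencyError(TriageDcaError):
    """Published summary statistics imply an impossible confusion matrix."""


class DegenerateDataError(TriageDcaError):
    """A dataset cannot support the requested operation (e.g. no cases)."""
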