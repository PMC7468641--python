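"""Exception hierarchy for painsgrid.

All errors raised by the library derive from :class:`PainsGridError` so
callers (and the CLI) can catch validation problems with one handler.
"""


class PainsGridError(Exception):
    """Base class for all painsgrid errors."""


class AtlasSchemaError(PainsGridError):
    """An atlas document violates the JSON schema (missing/invalid field)."""


class AtlasIntegrityError(PainsGridError):
    """An atlas violates a structural invariant (e.g. duplicate cell_id)."""


class ScopeError(PainsGridError):
    """A scope expression cannot be resolved, or resolves to no cells."""


class DataValidationError(PainsGridError):
    """An observation table violates its contract (range, enum, duplicate)."""


class DegenerateInputError(PainsGridError):
    """A statistic is undefined on the given input (zero variance etc.)."""


class EmptyCohortError(PainsGridError):
    """A cohort-level statistic was requested on data with no painful cells."""
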