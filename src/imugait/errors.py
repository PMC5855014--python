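"""Exception hierarchy for the gait-extraction pipeline.

Every stage raises a subclass of :class:`GaitError` so the CLI can map
failures onto exit codes (2 = input/format, 3 = processing).
"""


class GaitError(Exception):
    """Base class for all pipeline errors."""


class FormatError(GaitError):
    """A file does not conform to the expected CSV dialect."""


class IntegrityError(GaitError):
    """Parsed data violates an invariant (e.g. non-monotonic clock)."""


class ParameterError(GaitError):
    """An operation received an invalid parameter value."""


class InputError(GaitError):
    """An operation received structurally invalid input data."""


class SynchronizationError(GaitError):
    """Two recordings share no common time window."""


class SpecError(GaitError):
    """A synthetic-gait specification is infeasible or inconsistent."""
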