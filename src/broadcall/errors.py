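"""Exception hierarchy for broadcall.

Every user-facing failure maps onto one of these so the CLI can exit with a
categorized message instead of a traceback.
"""


class BroadcallError(Exception):
    """Base class for all broadcall errors."""


class ConfigurationError(BroadcallError):
    """Invalid parameter combination or malformed configuration."""


class DimensionError(BroadcallError):
    """Mismatched window grids, array shapes or sample counts."""


class DegenerateDataError(BroadcallError):
    """Data that cannot support model fitting (e.g. all-constant coverage)."""


class StateCollapseError(BroadcallError):
    """An HMM state received zero posterior weight where an update needs it."""


class NumericalError(BroadcallError):
    """Non-finite likelihood or other numerical breakdown during fitting."""


class UndefinedMetricError(BroadcallError):
    """An interval metric whose denominator is empty (no truth / no calls)."""


class InputError(BroadcallError):
    """Unreadable, unsorted or otherwise unusable input file."""
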