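"""Exception hierarchy for platekin."""


class PlatekinError(Exception):
    """Base class for all platekin errors."""


class InvalidSpecError(PlatekinError, ValueError):
    """A generator or protocol specification violates its invariants."""


class EmptyStreamError(PlatekinError, ValueError):
    """An event stream contains no events (or an empty epoch was required)."""


class SaturationError(PlatekinError, ValueError):
    """Fura-Red ratio at or above R_max: calcium is undefined."""


class IncompleteProtocolError(PlatekinError, ValueError):
    """The trace does not cover a protocol epoch needed for calibration."""


class OutOfRegimeError(PlatekinError, ValueError):
    """Chemical conditions outside the validity regime of a solver."""


class ConvergenceError(PlatekinError, RuntimeError):
    """An iterative solver (steady state, root-find) failed to converge."""
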