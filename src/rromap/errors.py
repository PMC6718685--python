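"""Exception types raised across the package."""


class InvalidParameterError(ValueError):
    """A model, feedback, or drive parameter violates its domain."""


class NoExtremumError(RuntimeError):
    """No interior local extremum of the map exists on the search interval."""


class BracketingError(ValueError):
    """A bisection bracket does not straddle the condition change."""


class UndefinedCorrelationError(RuntimeError):
    """Signal or response series has zero variance; C(tau) is undefined."""


class NoThresholdError(RuntimeError):
    """The scanned predicate never (or always) holds along the axis."""
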