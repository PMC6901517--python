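"""Exception hierarchy shared across the toolkit."""


class DQSError(Exception):
    """Base class for all toolkit errors."""


class InvalidModelError(DQSError, ValueError):
    """Model constants violate a validity constraint (e.g. non-positive rate)."""


class NoActiveBandError(DQSError, ValueError):
    """Circuit constants admit no phase-leading frequency window."""


class InsufficientDataError(DQSError, ValueError):
    """A record is too short for the requested estimate."""


class NonStationaryError(DQSError, RuntimeError):
    """The trailing window of a record fails the stationarity check."""


class ConfigError(DQSError, ValueError):
    """Simulation configuration violates a stability or consistency bound."""


class DivergentDensityError(DQSError, ArithmeticError):
    """The gain condition cannot be met at any finite cell count."""


class NumericalError(DQSError, RuntimeError):
    """An integration or root-finding step failed; carries diagnostic state."""
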