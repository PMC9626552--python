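"""Exception hierarchy for hepaflux."""


class HepafluxError(ValueError):
    """Base class for all hepaflux errors."""


class TraceError(HepafluxError):
    """Malformed oxygen trace (non-monotone time, non-finite values, ...)."""


class ProtocolError(HepafluxError):
    """Titration events do not match the SUIT protocol."""


class UndefinedValueError(HepafluxError):
    """A ratio or index is undefined for the given inputs (e.g. zero denominator)."""


class DesignError(HepafluxError):
    """Regression design problem: singular, zero-variance or underdetermined."""


class SimulationError(HepafluxError):
    """Synthetic-data generation failed (e.g. oxygen exhaustion mid-protocol)."""
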