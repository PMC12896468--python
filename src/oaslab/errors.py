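"""Exception hierarchy for oaslab.

All domain errors derive from :class:`OaslabError` so callers can catch the
whole family; most also derive from ``ValueError`` because they signal
invalid inputs rather than internal failures.
"""


class OaslabError(Exception):
    """Base class for all oaslab errors."""


class InvalidArgumentError(OaslabError, ValueError):
    """An argument violates a documented precondition."""


class PlacementInfeasibleError(OaslabError, RuntimeError):
    """Rejection sampling could not place the requested shapes."""


class HorizonExceededError(OaslabError, ValueError):
    """Requested record length would be contaminated by periodic wraparound.

    The spectral propagator solves the wave equation on a zero-padded
    periodic domain; beyond a geometry-dependent time horizon, periodic
    image sources reach the sensors and the output would be silently wrong.
    """


class IncompatibleWaveformError(OaslabError, ValueError):
    """Waveforms with mismatched sampling cannot be combined."""


class TruncationError(OaslabError, ValueError):
    """The requested time window is too short to contain the signal."""


class AliasingError(OaslabError, ValueError):
    """The waveform is undersampled for the requested filtering."""


class NoSignalError(OaslabError, ValueError):
    """A profile contains no strictly positive sample to threshold."""


class NoExtremumError(OaslabError, ValueError):
    """A constant signal has no well-defined extremum."""


class DegenerateFitError(OaslabError, ValueError):
    """A regression with constant predictor is undefined."""
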