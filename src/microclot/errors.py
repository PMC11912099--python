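"""Exception hierarchy for the micro-clot dissolution pipeline.

Every error raised by the library derives from :class:`MicroclotError`, so
callers (and the plate-level driver, which must isolate per-well failures)
can catch one base class.
"""


class MicroclotError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(MicroclotError, ValueError):
    """An argument violates an operation's precondition."""


class ConfigurationError(MicroclotError, ValueError):
    """A run configuration (plate map, config file, condition table) is invalid."""


class DegenerateThresholdError(MicroclotError):
    """Automatic thresholding failed because the frame carries no contrast."""


class NoObjectError(MicroclotError):
    """The binary foreground is empty; there is no object to isolate."""


class UndersizedMaskError(MicroclotError):
    """The segmented region is implausibly small and was rejected."""


class InvalidFrameError(MicroclotError):
    """A frame cannot yield the intensity statistic (e.g. zero background mean)."""


class UnusableFitError(MicroclotError):
    """A kinetic fit did not converge and cannot provide readouts."""


class DegenerateVarianceError(MicroclotError):
    """Group comparison is impossible because within-group variance is zero."""
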