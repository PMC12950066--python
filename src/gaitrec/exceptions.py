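"""Exception hierarchy for the gaitrec pipeline.

Every stage raises a subclass of :class:`GaitrecError` so callers can
distinguish pipeline failures from programming errors.
"""


class GaitrecError(Exception):
    """Base class for all gaitrec errors."""


class FormatError(GaitrecError):
    """A file does not conform to the expected on-disk dialect."""


class DataError(GaitrecError):
    """Input data violates an invariant (e.g. non-finite samples)."""


class ConfigError(GaitrecError):
    """A configuration object is internally inconsistent or infeasible."""


class StateError(GaitrecError):
    """An operation was applied to data in the wrong state
    (e.g. normalizing twice, predicting on unnormalized windows)."""


class SplitError(GaitrecError):
    """A participant split cannot be constructed or is inconsistent."""


class BalanceError(GaitrecError):
    """Class balancing was requested but a class is absent."""


class RatioError(GaitrecError):
    """A class ratio is undefined (no walking windows)."""
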