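"""Exception hierarchy for tramqc.

All errors raised on bad input derive from :class:`TramQCError` so callers
can catch the package's failures with a single ``except`` clause.
"""


class TramQCError(Exception):
    """Base class for all tramqc errors."""


class TrackTableFormatError(TramQCError):
    """A track table is missing a mapped column or cannot be parsed."""


class TrackIntegrityError(TramQCError):
    """Duplicate (cell, time) rows, missing TrAM results, or similar."""


class ConfigurationError(TramQCError):
    """Invalid parameters, unset experiment length, unknown statistic, ..."""


class DriftEstimationError(TramQCError):
    """Global drift cannot be estimated (no complete tracks)."""


class CalibrationError(TramQCError):
    """ROC calibration impossible (e.g. only one annotation class)."""
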