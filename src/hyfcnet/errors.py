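"""Exception hierarchy for hyfcnet.

All package errors derive from :class:`HyfcnetError`, so callers can catch
one base class at pipeline boundaries while still discriminating the
specific failure mode.
"""


class HyfcnetError(Exception):
    """Base class for all hyfcnet errors."""


class InvalidWindowError(HyfcnetError, ValueError):
    """Sliding-window parameters inconsistent with the series length."""


class DegenerateSignalError(HyfcnetError, ValueError):
    """A time-series column is constant over a window, so Pearson
    correlation is undefined for that ROI."""


class DegenerateProfileError(HyfcnetError, ValueError):
    """A connectivity-profile column is constant, so the correlation of
    profiles is undefined."""


class StaticInputError(HyfcnetError, ValueError):
    """An operation that needs a dynamic (multi-window) network set was
    given a static one (K = 1)."""


class ShapeError(HyfcnetError, ValueError):
    """Array dimensions do not match what the operation requires."""


class InvalidWeightError(HyfcnetError, ValueError):
    """Graph weights or kernel weights violate their constraints
    (negative edge weight, kernel weights off the probability simplex)."""


class AsymmetryError(HyfcnetError, ValueError):
    """A matrix expected to be symmetric is asymmetric beyond tolerance."""


class DegenerateLabelsError(HyfcnetError, ValueError):
    """A training fold contains a single class."""


class InsufficientDataError(HyfcnetError, ValueError):
    """Too few subjects for the requested fit."""


class UndefinedSeparabilityError(HyfcnetError, ValueError):
    """Separability (r²) is undefined because the values have zero
    variance across subjects."""


class MissingScoresError(HyfcnetError, ValueError):
    """AUC requested but no decision values supplied."""


class InvalidConfigError(HyfcnetError, ValueError):
    """A configuration value is out of its legal range or an option grid
    is empty."""


class ManifestError(HyfcnetError, ValueError):
    """A cohort manifest is malformed or references missing/inconsistent
    subject files."""
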