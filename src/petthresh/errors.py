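"""Exception hierarchy.

All package errors derive from :class:`PetThreshError` so callers can catch
one base class; subclasses also derive from the closest builtin category
(``ValueError``/``RuntimeError``) for idiomatic handling.
"""


class PetThreshError(Exception):
    """Base class for all errors raised by petthresh."""


class GeometryError(PetThreshError, ValueError):
    """ROI/mask/image geometry is inconsistent (bounds, shape, degeneracy)."""


class EmptyRegionError(PetThreshError, ValueError):
    """An operation requiring a non-empty pixel region received an empty one."""


class ModelDomainError(PetThreshError, ValueError):
    """A threshold-adjustment function was evaluated outside its domain
    (non-positive base of a power law, Bmin <= 0, wrong predictor)."""


class DegenerateFitError(PetThreshError, ValueError):
    """Regression cannot be performed (too few samples, singular design,
    zero variance in the response)."""


class NoFeasibleThresholdError(PetThreshError, RuntimeError):
    """No candidate threshold produced a usable region during calibration."""


class NoLesionFoundError(PetThreshError, RuntimeError):
    """Every slice of a stack segmented degenerately; no lesion to report."""


class InvalidReferenceError(PetThreshError, ValueError):
    """A reference measurement (denominator of a relative difference) is
    missing or non-positive."""


class EmptyTableError(PetThreshError, ValueError):
    """A summary statistic was requested on an empty record collection."""
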