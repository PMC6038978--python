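"""Exception hierarchy for the quantification pipeline."""


class MibgQuantError(Exception):
    """Base class for all pipeline errors."""


class NoBolusDetected(MibgQuantError):
    """No pixel in the dynamic series passed the bolus amplitude gate."""


class RoiOutOfBounds(MibgQuantError):
    """A region of interest extends beyond the image grid."""


class FitFailed(MibgQuantError):
    """Gamma-variate fitting did not converge from any initialization."""


class ZeroMediastinum(MibgQuantError):
    """Mediastinal mean counts are zero; H/M undefined."""


class ZeroAuc(MibgQuantError):
    """Input-function AUC is non-positive; uptake index undefined."""


class IndivisibleSubsets(MibgQuantError):
    """Number of projection views is not divisible by the subset count."""


class AxisUndetermined(MibgQuantError):
    """Myocardial long axis could not be estimated and no template given."""


class EmptySlice(MibgQuantError):
    """A polar-map ring has no in-grid samples."""


class TooFewPairs(MibgQuantError):
    """Calibration requires at least three count pairs."""


class DegenerateX(MibgQuantError):
    """Calibration regressor values are all zero."""


class InvalidCalibration(MibgQuantError):
    """Conversion factor must be positive."""


class TooFewValues(MibgQuantError):
    """Group summary requires at least two values."""


class EmptyGroup(MibgQuantError):
    """A patient group contains no values."""


class EmptySample(MibgQuantError):
    """A statistical test received an empty sample."""


class OneClassOnly(MibgQuantError):
    """ROC analysis requires both classes to be present."""


class NegativeCount(MibgQuantError):
    """Contingency tables require nonnegative integer counts."""


class LengthMismatch(MibgQuantError):
    """Paired vectors must have equal length."""
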