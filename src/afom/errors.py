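"""Exception hierarchy for the AFOM pipeline.

Every error raised on a contract violation derives from :class:`AfomError`
so callers (and the CLI) can catch pipeline failures without swallowing
programming errors.
"""


class AfomError(Exception):
    """Base class for all pipeline errors."""


class WavelengthLookupError(AfomError):
    """No grid point lies within tolerance of the requested wavelength."""


class AxisAlignmentError(AfomError):
    """Two EEMs that must share a wavelength grid do not."""


class RangeError(AfomError):
    """A crop or band selects no grid points."""


class EEMParseError(AfomError):
    """A delimited-text EEM or absorbance file is malformed."""


class CoverageError(AfomError):
    """An absorbance spectrum does not cover a requested wavelength."""


class UnitError(AfomError):
    """An operation received an EEM in the wrong intensity unit."""


class QualityError(AfomError):
    """Too much of a peak band is masked to report a mean."""


class InputError(AfomError):
    """Inconsistent or missing tabular input (times, replicates, labels)."""


class UndefinedBaselineError(InputError):
    """Percent change requested against a zero baseline."""


class UndefinedFractionError(InputError):
    """Fraction table requested for an all-zero peak triple."""


class InsufficientDataError(InputError):
    """Too few observations for the requested computation."""


class ParameterError(AfomError):
    """A simulation or configuration parameter is out of range."""


class ConfigError(AfomError):
    """A run configuration file is invalid; the message names the key."""
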