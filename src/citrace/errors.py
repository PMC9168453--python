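"""Exception hierarchy shared across the package."""


class CitraceError(Exception):
    """Base class for all package-specific errors."""


class UndefinedRatioError(CitraceError):
    """A citrate carbon ratio is requested with a zero denominator."""


class ModelRangeError(CitraceError):
    """Observed ratios lie outside the range the two-parameter model can attain."""


class MultipleRootsError(CitraceError):
    """The inversion found more than one (d, p) candidate on the search grid."""


class ConfigurationError(CitraceError):
    """A required quantification setting is missing or invalid."""


class FitError(CitraceError):
    """A spectral fit failed to converge or its window is absent."""


class LowSignalError(FitError):
    """The fit window contains no signal distinguishable from noise."""
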