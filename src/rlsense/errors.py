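"""Exception hierarchy for rlsense.

All package errors derive from :class:`RLSenseError`; value/precondition
violations additionally derive from :class:`ValueError` so callers that do not
know about rlsense still catch them idiomatically.
"""


class RLSenseError(Exception):
    """Base class for all rlsense errors."""


class DomainError(RLSenseError, ValueError):
    """A numeric argument is outside the model's domain (e.g. g >= 1)."""


class DataError(RLSenseError, ValueError):
    """Input data violate a structural contract (empty group, bad header...)."""


class NoLasingError(DataError):
    """The peak-wavelength series has no blueshift-to-redshift turning point."""


class InsufficientPointsError(DataError):
    """Too few usable points survive filtering for the requested operation."""


class FeatureError(DataError):
    """Spectral feature extraction failed (no unique peak, truncated line)."""


class ConfigError(RLSenseError, ValueError):
    """Generator or pipeline configuration is invalid."""


class FitError(RLSenseError):
    """Nonlinear fit failed to converge.

    Carries the best parameters seen so far (may be ``None``) so diagnostics
    can still be reported.
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best
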