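"""Invert the calibrated sensing model to estimate optical properties.

A single sample's lasing-regime series (dE, dlp) determines, through the
calibrated model, only the lumped combination

    L = mu_s' / (1 + r * mu_a)    [1/cm],

the slope of dlp against (1 - exp(-b*dE)) / k.  Recovering mu_a additionally
requires a known mu_s' (and vice versa); that conditional recovery is made
explicit here rather than pretending both coefficients are separately
identifiable from one series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibrate import EPS_DELTA_LAMBDA
from .errors import DomainError, InsufficientPointsError
from .model import CalibratedModel
from .preprocess import LasingSegment

__all__ = [
    "SensingEstimate",
    "estimate_lumped",
    "recover_mu_a",
    "recover_mu_s_prime",
    "estimate_properties",
]


@dataclass
class SensingEstimate:
    """Optical-property estimate for one sample.

    ``L_hat`` is the identifiable lump mu_s'/(1+r*mu_a) with its standard
    error; ``mu_a_hat`` / ``mu_s_prime_hat`` are present only when the
    complementary coefficient was supplied.  A negative recovered mu_a is
    flagged (``mu_a_outside_model_domain``), never silently clipped.
    """

    sample_id: str
    L_hat: float
    se: float
    n_points: int
    mu_a_hat: float | None = None
    mu_s_prime_hat: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.L_hat > 0:
            raise DomainError(f"L_hat must be positive, got {self.L_hat}")


def estimate_lumped(seg: LasingSegment, model: CalibratedModel) -> SensingEstimate:
    """Estimate L = mu_s'/(1+r*mu_a) from one lasing segment.

    Through-origin least squares of ``dlp`` on ``(1 - exp(-b*dE))/k`` (the
    model forces dlp = 0 at dE = 0).  Points with ``dlp <= EPS_DELTA_LAMBDA``
    or ``dE <= 0`` are excluded; at least 3 must survive.
    """
    usable = (seg.delta_lambda_p > EPS_DELTA_LAMBDA) & (seg.delta_E > 0)
    n = int(usable.sum())
    if n < 3:
        raise InsufficientPointsError(
            f"sample {seg.sample_id}: only {n} usable points for inversion, need 3"
        )
    x = (1.0 - np.exp(-model.b * seg.delta_E[usable])) / model.k
    y = seg.delta_lambda_p[usable]
    sxx = float(np.sum(x * x))
    slope = float(np.sum(x * y) / sxx)
    resid = y - slope * x
    se = float(np.sqrt(np.sum(resid**2) / (max(n - 1, 1) * sxx)))
    return SensingEstimate(sample_id=seg.sample_id, L_hat=slope, se=se, n_points=n)


def recover_mu_a(L_hat: float, mu_s_prime_known: float, r: float) -> float:
    """Absorption coefficient from the lump and a known mu_s'.

    ``mu_a = (mu_s'/L - 1) / r``.  A negative result signals inputs outside
    the model domain (L above the zero-absorption value); it is returned
    as-is for the caller to flag.
    """
    if r == 0:
        raise DomainError("r must be nonzero")
    if not (L_hat > 0 and mu_s_prime_known > 0):
        raise DomainError("L_hat and mu_s_prime_known must be positive")
    return (mu_s_prime_known / L_hat - 1.0) / r


def recover_mu_s_prime(L_hat: float, mu_a_known: float, r: float) -> float:
    """Reduced scattering coefficient from the lump and a known mu_a:
    ``mu_s' = L * (1 + r*mu_a)``."""
    if not L_hat > 0:
        raise DomainError("L_hat must be positive")
    if mu_a_known < 0:
        raise DomainError("mu_a_known must be non-negative")
    return L_hat * (1.0 + r * mu_a_known)


def estimate_properties(
    seg: LasingSegment,
    model: CalibratedModel,
    known_mu_s_prime: float | None = None,
    known_mu_a: float | None = None,
) -> SensingEstimate:
    """Lumped estimate plus conditional recovery of mu_a and/or mu_s'."""
    est = estimate_lumped(seg, model)
    if known_mu_s_prime is not None:
        mu_a = recover_mu_a(est.L_hat, known_mu_s_prime, model.r)
        est.mu_a_hat = mu_a
        if mu_a < 0:
            est.flags.append("mu_a_outside_model_domain")
    if known_mu_a is not None:
        est.mu_s_prime_hat = recover_mu_s_prime(est.L_hat, known_mu_a, model.r)
    return est
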