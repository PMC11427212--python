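"""Algebraic core of the diffuse-reflectance random-laser (DRS-RL) sensing model.

A random laser (RL) pumped in a turbid medium and observed in the
backscattered direction behaves like diffuse reflectance with gain.  The
diffuse reflectance of a semi-infinite turbid medium probed with a fiber
geometry is taken in the Zonios form

    Rd = mu_s' / (k1 + k2 * mu_a),

where ``k1`` (dimensionless) and ``k2`` (cm, so that ``k2*mu_a`` is
dimensionless) are geometry scaling parameters.  Above the lasing threshold
the peak-wavelength shift ``dlp = lambda_p - lambda_th`` factorizes into an
optical-property part and a universal gain part,

    dlp = (1/k) * mu_s' / (1 + r*mu_a) * (1 - exp(-b*dE)),

with ``k`` a general scaling factor, ``r = k2/k1`` (cm) the
absorption-to-scattering slope and ``b`` (1/mJ) the gain rate; ``dE`` is the
pump energy above threshold in mJ.  Units throughout the package: energies in
mJ, wavelengths in nm, optical coefficients in 1/cm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

__all__ = [
    "OpticalProperties",
    "ZoniosParams",
    "GainCurve",
    "CalibratedModel",
    "REFERENCE_MODEL",
    "reduced_from_scattering",
    "zonios_reflectance",
    "collapsed_value",
    "forward_delta_lambda",
    "lumped_parameter",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of one turbid sample.

    Parameters
    ----------
    mu_s_prime
        Reduced scattering coefficient mu_s' in 1/cm; must be positive.
    mu_a
        Absorption coefficient in 1/cm; non-negative.
    g
        Optional anisotropy factor (mean cosine of the single-scattering
        angle), in [0, 1).
    mu_s
        Optional scattering coefficient in 1/cm.  When both ``mu_s`` and
        ``g`` are given they must be consistent with
        ``mu_s_prime = mu_s * (1 - g)``.
    """

    mu_s_prime: float
    mu_a: float
    g: float | None = None
    mu_s: float | None = None

    def __post_init__(self) -> None:
        if not self.mu_s_prime > 0:
            raise DomainError(f"mu_s_prime must be positive, got {self.mu_s_prime}")
        if self.mu_a < 0:
            raise DomainError(f"mu_a must be non-negative, got {self.mu_a}")
        if self.g is not None and not (0.0 <= self.g < 1.0):
            raise DomainError(f"anisotropy g must lie in [0, 1), got {self.g}")
        if self.mu_s is not None and not self.mu_s > 0:
            raise DomainError(f"mu_s must be positive, got {self.mu_s}")
        if self.mu_s is not None and self.g is not None:
            if abs(self.mu_s_prime - self.mu_s * (1.0 - self.g)) > 1e-9 * self.mu_s_prime:
                raise DomainError(
                    "inconsistent scattering parameters: "
                    f"mu_s*(1-g)={self.mu_s * (1.0 - self.g)} != mu_s_prime={self.mu_s_prime}"
                )

    @property
    def ls(self) -> float | None:
        """Scattering mean free path 1/mu_s in cm (None when mu_s unknown)."""
        return None if self.mu_s is None else 1.0 / self.mu_s

    @property
    def ls_prime(self) -> float:
        """Reduced scattering mean free path 1/mu_s' in cm."""
        return 1.0 / self.mu_s_prime

    @property
    def in_diffusion_regime(self) -> bool:
        """True when mu_s' >= 10 * mu_a, the regime the reflectance model assumes."""
        return self.mu_s_prime >= 10.0 * self.mu_a


@dataclass(frozen=True)
class ZoniosParams:
    """Geometry scaling parameters of the diffuse-reflectance model.

    ``k1`` is dimensionless, ``k2`` carries cm so that ``k2*mu_a`` is
    dimensionless.  Only their ratio is identifiable from curve collapse.
    """

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not (self.k1 > 0 and self.k2 > 0):
            raise DomainError(f"k1 and k2 must be positive, got ({self.k1}, {self.k2})")


@dataclass(frozen=True)
class GainCurve:
    """Exponential gain curve ``y = -a*exp(-b*x) + c``.

    ``a`` and ``c`` share the units of the collapsed ordinate; ``b`` is the
    gain rate in 1/mJ.  A curve through the origin has ``c == a``.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise DomainError(f"gain rate b must be positive, got {self.b}")

    def predict(self, x) -> np.ndarray:
        """Evaluate the curve at pump-energy offsets ``x`` (mJ)."""
        return -self.a * np.exp(-self.b * np.asarray(x, dtype=float)) + self.c


@dataclass(frozen=True)
class CalibratedModel:
    """Fully calibrated sensing model ``k*dlp*(1+r*mu_a)/mu_s' = 1 - exp(-b*dE)``.

    Attributes
    ----------
    k
        General scaling factor (dimensionless composite of geometry and gain).
    r
        Absorption-to-scattering slope k2/k1 in cm.
    b
        Gain rate in 1/mJ.
    """

    k: float
    r: float
    b: float

    def __post_init__(self) -> None:
        if not (self.k > 0 and self.r > 0 and self.b > 0):
            raise DomainError(f"k, r, b must all be positive, got ({self.k}, {self.r}, {self.b})")


#: Calibration reported in the literature for the original fiber-probe
#: geometry (Intralipid/ink phantoms, R6G gain): k = 9.59, r = 0.36 cm,
#: b = 0.034 1/mJ.  Used as the default ground truth of the synthetic
#: generator.
REFERENCE_MODEL = CalibratedModel(k=9.59, r=0.36, b=0.034)


def reduced_from_scattering(mu_s: float, g: float) -> float:
    """Reduced scattering coefficient ``mu_s' = mu_s * (1 - g)``.

    Parameters are the scattering coefficient (1/cm, positive) and the
    anisotropy factor in [0, 1).
    """
    if not mu_s > 0:
        raise DomainError(f"mu_s must be positive, got {mu_s}")
    if not (0.0 <= g < 1.0):
        raise DomainError(f"anisotropy g must lie in [0, 1), got {g}")
    return mu_s * (1.0 - g)


def zonios_reflectance(op: OpticalProperties, zp: ZoniosParams) -> float:
    """Diffuse reflectance ``Rd = mu_s' / (k1 + k2*mu_a)``.

    Strictly increasing in mu_s' and strictly decreasing in mu_a; homogeneous
    of degree -1 in (k1, k2) jointly.
    """
    denom = zp.k1 + zp.k2 * op.mu_a
    if denom == 0:
        raise DomainError("k1 + k2*mu_a must be nonzero")
    return op.mu_s_prime / denom


def collapsed_value(delta_lambda_p, op: OpticalProperties, zp: ZoniosParams):
    """Reflectance-corrected peak shift ``dlp * (k1 + k2*mu_a) / mu_s'``.

    Dividing the shift by Rd removes the optical-property effect; for the
    correct ratio k2/k1 all samples collapse onto one gain curve.  Accepts a
    scalar or array ``delta_lambda_p`` (nm, non-negative).
    """
    dlp = np.asarray(delta_lambda_p, dtype=float)
    if np.any(dlp < 0):
        raise DomainError("delta_lambda_p must be non-negative")
    out = dlp * (zp.k1 + zp.k2 * op.mu_a) / op.mu_s_prime
    return float(out) if np.isscalar(delta_lambda_p) else out


def forward_delta_lambda(op: OpticalProperties, delta_E, model: CalibratedModel):
    """Peak-wavelength shift predicted by the calibrated sensing model.

    ``dlp = (1/k) * mu_s'/(1 + r*mu_a) * (1 - exp(-b*dE))`` for pump energy
    ``delta_E`` (mJ) above the lasing threshold.  Zero at ``delta_E = 0``,
    strictly increasing and concave in ``delta_E``, with asymptote
    ``mu_s' / (k * (1 + r*mu_a))``.  Below-threshold (negative) energies are
    outside the model and rejected.
    """
    dE = np.asarray(delta_E, dtype=float)
    if np.any(dE < 0):
        raise DomainError("delta_E must be non-negative (lasing regime only)")
    out = lumped_parameter(op, model.r) / model.k * (1.0 - np.exp(-model.b * dE))
    return float(out) if np.isscalar(delta_E) else out


def lumped_parameter(op: OpticalProperties, r: float) -> float:
    """Identifiable optical-property combination ``L = mu_s' / (1 + r*mu_a)`` (1/cm).

    A single sample's lasing-regime shift determines only this lump; see the
    inversion module for conditional recovery of mu_a or mu_s'.
    """
    if not r > 0:
        raise DomainError(f"r must be positive, got {r}")
    return op.mu_s_prime / (1.0 + r * op.mu_a)
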