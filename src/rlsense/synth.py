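"""Synthetic random-laser peak-series generator with stored ground truth.

Emulates the study conditions of the Intralipid/ink phantom measurements:
two Intralipid levels (mu_s' = 63.78 and 106.13 1/cm), ink absorption mu_a
from 0 to 8.64 1/cm, pump energies from 1.82 to 40.86 mJ on a half-Gaussian
grid (denser at low energy), five replicate shots per point.  Below the
lasing threshold the peak wavelength blueshifts toward the threshold value;
at and above threshold it redshifts following the calibrated sensing model,
optionally damped by a gain-saturation factor.  Every dataset carries its
ground truth (per-sample thresholds, the truth model, noise level, seed) so
each pipeline stage can be tested by recovery.

The threshold and below-threshold functional forms are package inventions
constrained only by the qualitative phenomenology (higher absorption raises
the threshold and blueshifts the peak; stronger scattering does the
opposite); all their constants live in :class:`GeneratorConfig` and are
stored with the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibrate import CollapseDataset
from .errors import ConfigError, DataError, DomainError
from .model import CalibratedModel, OpticalProperties, REFERENCE_MODEL, forward_delta_lambda
from .preprocess import Spectrum

__all__ = [
    "IL_ANCHORS",
    "INK_ANCHOR",
    "SampleSpec",
    "GeneratorConfig",
    "SampleTruth",
    "SyntheticTruth",
    "ops_from_concentrations",
    "study_sample_grid",
    "pump_grid",
    "threshold_model",
    "generate_peak_series",
    "generate_study_dataset",
    "generate_spectrum",
    "perturb_delta_lambda",
]

#: (Intralipid % v/v, mu_s' 1/cm) anchor pairs; interpolation between them.
IL_ANCHORS = ((5.0, 63.78), (9.0, 106.13))
#: (ink % v/v, mu_a 1/cm) anchor; mu_a proportional through the origin.
INK_ANCHOR = (0.09, 8.64)


@dataclass(frozen=True)
class SampleSpec:
    """One phantom recipe: Intralipid and ink concentrations plus derived OPs."""

    il_percent: float
    ink_percent: float
    op: OpticalProperties

    @property
    def sample_id(self) -> str:
        return f"IL{self.il_percent:g}_ink{self.ink_percent:.4f}"


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic generator (defaults are the study conditions).

    Energies in mJ, wavelengths in nm, coefficients in 1/cm.  ``E0`` is the
    lasing threshold of the reference sample (mu_s' = mu_s_prime_ref, no
    absorber); ``c_a``/``c_s`` set how the threshold wavelength responds to
    absorption and scattering.  ``saturation`` is an optional
    ``(s, E_sat_mJ)`` pair multiplying the above-threshold shift by
    ``1 - s*dE/(dE + E_sat)``.  ``seed`` is mandatory.
    """

    seed: int
    E_min: float = 1.82
    E_max: float = 40.86
    n_energies: int = 30
    spacing: str = "half-gaussian"
    n_replicates: int = 5
    sigma_lambda: float = 0.05
    truth_model: CalibratedModel = REFERENCE_MODEL
    E0: float = 4.0
    mu_s_prime_ref: float = 63.78
    blueshift_depth: float = 1.5
    blueshift_exponent: float = 1.0
    c_a: float = 0.2
    c_s: float = 1.0
    lambda0: float = 565.0
    saturation: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.E_min < self.E_max:
            raise ConfigError("E_min must be below E_max")
        if self.n_energies < 5:
            raise ConfigError("need at least 5 pump energies")
        if self.spacing not in ("half-gaussian", "linear"):
            raise ConfigError(f"unknown spacing {self.spacing!r}")
        if self.n_replicates < 1 or self.sigma_lambda < 0:
            raise ConfigError("invalid replicate count or noise level")
        for name in ("E0", "mu_s_prime_ref", "blueshift_depth", "c_a", "c_s", "lambda0"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass(frozen=True)
class SampleTruth:
    """Ground truth for one generated sample."""

    sample_id: str
    op: OpticalProperties
    E_th: float  # snapped to the pump grid
    lambda_th: float
    E_th_continuous: float


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth stored alongside a generated dataset."""

    samples: dict[str, SampleTruth]
    truth_model: CalibratedModel
    sigma_lambda: float
    seed: int


def ops_from_concentrations(
    il_percent: float, ink_percent: float, allow_extrapolation: bool = False
) -> OpticalProperties:
    """Optical properties from phantom concentrations via the anchor values.

    mu_s' interpolates linearly between the (5%, 63.78) and (9%, 106.13)
    anchors (they are not proportional through the origin); mu_a is
    proportional through the (0.09%, 8.64) anchor, i.e. 96 * ink%.
    Concentrations outside the anchored ranges are refused unless
    ``allow_extrapolation`` is set.
    """
    (il_lo, msp_lo), (il_hi, msp_hi) = IL_ANCHORS
    ink_hi, mua_hi = INK_ANCHOR
    if not allow_extrapolation:
        if not (il_lo <= il_percent <= il_hi):
            raise DomainError(
                f"Intralipid {il_percent}% outside anchored range [{il_lo}, {il_hi}]"
            )
        if not (0.0 <= ink_percent <= ink_hi):
            raise DomainError(f"ink {ink_percent}% outside anchored range [0, {ink_hi}]")
    t = (il_percent - il_lo) / (il_hi - il_lo)
    mu_s_prime = msp_lo + t * (msp_hi - msp_lo)
    mu_a = mua_hi / ink_hi * ink_percent
    return OpticalProperties(mu_s_prime=mu_s_prime, mu_a=mu_a)


def study_sample_grid(n_ink: int = 5) -> list[SampleSpec]:
    """The 2 x n_ink study grid: both Intralipid anchors crossed with ink
    levels evenly spaced from 0 to the 0.09% anchor."""
    specs = []
    for il, _ in IL_ANCHORS:
        for ink in np.linspace(0.0, INK_ANCHOR[0], n_ink):
            specs.append(SampleSpec(il, float(ink), ops_from_concentrations(il, float(ink))))
    return specs


def pump_grid(config: GeneratorConfig) -> np.ndarray:
    """Pump-energy grid between E_min and E_max.

    ``half-gaussian`` spacing places the points at half-normal quantiles
    affinely rescaled to [E_min, E_max]: sampling is denser at low energy
    (the grid median lies below the interval midpoint) and both endpoints
    are hit exactly.  ``linear`` gives equal spacing.
    """
    n = config.n_energies
    if config.spacing == "linear":
        return np.linspace(config.E_min, config.E_max, n)
    u = np.arange(1, n + 1) / (n + 1)
    q = stats.halfnorm.ppf(u)
    q = (q - q[0]) / (q[-1] - q[0])
    return config.E_min + (config.E_max - config.E_min) * q


def threshold_model(op: OpticalProperties, config: GeneratorConfig) -> tuple[float, float]:
    """Continuous lasing threshold and threshold wavelength for one sample.

    ``E_th = E0 * (1 + r*mu_a) * (mu_s'_ref / mu_s')`` — absorption raises
    the threshold, scattering lowers it.  ``lambda_th = lambda0 - c_a*mu_a +
    c_s*(mu_s' - mu_s'_ref)/mu_s'_ref`` — ink blueshifts, Intralipid
    redshifts.  The threshold must be probeable: inside
    (E_min, 0.8 * E_max).
    """
    E_th = config.E0 * (1.0 + config.truth_model.r * op.mu_a) * (
        config.mu_s_prime_ref / op.mu_s_prime
    )
    lambda_th = (
        config.lambda0
        - config.c_a * op.mu_a
        + config.c_s * (op.mu_s_prime - config.mu_s_prime_ref) / config.mu_s_prime_ref
    )
    if not (config.E_min < E_th < 0.8 * config.E_max):
        raise ConfigError(
            f"threshold {E_th:.2f} mJ not probeable in ({config.E_min}, {0.8 * config.E_max:.2f})"
        )
    return E_th, lambda_th


def _noiseless_lambda(E: np.ndarray, truth: SampleTruth, op, config) -> np.ndarray:
    lam = np.empty_like(E)
    below = E < truth.E_th
    lam[below] = truth.lambda_th + config.blueshift_depth * (
        1.0 - E[below] / truth.E_th
    ) ** config.blueshift_exponent
    dE = E[~below] - truth.E_th
    shift = forward_delta_lambda(op, dE, config.truth_model)
    if config.saturation is not None:
        s, E_sat = config.saturation
        shift = shift * (1.0 - s * dE / (dE + E_sat))
    lam[~below] = truth.lambda_th + shift
    return lam


def generate_peak_series(
    spec: SampleSpec, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, SampleTruth]:
    """Generate per-shot peak records for one sample.

    The continuous threshold is snapped to the nearest grid energy and stored
    as truth, so on noiseless data the peak-wavelength minimum sits exactly
    on the threshold grid point and the above-threshold shifts follow the
    truth model exactly.  Per-shot Gaussian noise ``sigma_lambda`` (nm) is
    added to the peak wavelength; the FWHM channel collapses logistically
    from 30 nm to 0.3 nm at threshold and the intensity channel kinks from a
    shallow to a steep linear slope there (deterministic diagnostics).
    Returns a tidy per-shot DataFrame in the peak-table schema plus the
    sample truth.
    """
    E = pump_grid(config)
    E_th_cont, lambda_th = threshold_model(spec.op, config)
    # snap to the nearest interior grid energy: the turning point needs
    # probed points on both sides
    idx = int(np.clip(np.argmin(np.abs(E - E_th_cont)), 1, E.size - 2))
    E_th = float(E[idx])
    truth = SampleTruth(
        sample_id=spec.sample_id,
        op=spec.op,
        E_th=E_th,
        lambda_th=lambda_th,
        E_th_continuous=E_th_cont,
    )
    lam0 = _noiseless_lambda(E, truth, spec.op, config)
    fwhm = 0.3 + (30.0 - 0.3) / (1.0 + np.exp((E - E_th) / (0.05 * E_th)))
    i_th = 5.0 + 1.0 * E_th
    intensity = np.where(E < E_th, 5.0 + 1.0 * E, i_th + 50.0 * (E - E_th))

    rows = []
    for i, e in enumerate(E):
        for rep in range(1, config.n_replicates + 1):
            noise = rng.normal(0.0, config.sigma_lambda) if config.sigma_lambda > 0 else 0.0
            rows.append(
                {
                    "sample_id": spec.sample_id,
                    "il_percent": spec.il_percent,
                    "ink_percent": spec.ink_percent,
                    "mu_s_prime": spec.op.mu_s_prime,
                    "mu_a": spec.op.mu_a,
                    "replicate": rep,
                    "pump_energy_mJ": float(e),
                    "peak_wavelength_nm": float(lam0[i] + noise),
                    "fwhm_nm": float(fwhm[i]),
                    "peak_intensity": float(intensity[i]),
                }
            )
    return pd.DataFrame(rows), truth


def generate_study_dataset(
    config: GeneratorConfig, samples: list[SampleSpec] | None = None
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate the full study dataset (default: the 2 x 5 OP grid).

    A single seeded generator drives all samples in a fixed order, so two
    runs with the same config are identical.
    """
    rng = np.random.default_rng(config.seed)
    if samples is None:
        samples = study_sample_grid()
    frames, truths = [], {}
    for spec in samples:
        df, truth = generate_peak_series(spec, config, rng)
        frames.append(df)
        truths[spec.sample_id] = truth
    return (
        pd.concat(frames, ignore_index=True),
        SyntheticTruth(
            samples=truths,
            truth_model=config.truth_model,
            sigma_lambda=config.sigma_lambda,
            seed=config.seed,
        ),
    )


def generate_spectrum(
    lambda_p: float,
    fwhm: float,
    intensity: float,
    rng: np.random.Generator,
    baseline_noise: float = 0.0,
    half_window: float = 10.0,
    step: float = 0.05,
) -> Spectrum:
    """One Gaussian emission line sampled on a regular wavelength grid.

    Centered at ``lambda_p`` with the given FWHM and peak intensity, sampled
    every ``step`` nm over ``lambda_p +/- half_window``, plus optional
    additive Gaussian baseline noise.
    """
    if fwhm <= 0 or intensity <= 0:
        raise DataError("fwhm and intensity must be positive")
    w = np.arange(lambda_p - half_window, lambda_p + half_window + step / 2, step)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    y = intensity * np.exp(-0.5 * ((w - lambda_p) / sigma) ** 2)
    if baseline_noise > 0:
        y = y + rng.normal(0.0, baseline_noise, size=w.size)
    return Spectrum(wavelengths=w, intensities=y)


def study_collapse_dataset(
    seed: int,
    additive: float = 0.0,
    multiplicative: float = 0.0,
    config: GeneratorConfig | None = None,
    saturation_factor: float | None = 20.0,
) -> tuple[CollapseDataset, SyntheticTruth]:
    """Study-grid collapse dataset via the full preprocessing path.

    Generates the noiseless 2 x 5 OP-grid peak series, averages replicates,
    detects each sample's threshold from the turning point, converts to
    relative coordinates with the saturation cut, pools the segments, and
    finally injects the requested noise on ``delta_lambda_p`` (additive in
    nm and/or multiplicative relative sigma) with a generator derived from
    ``seed``.
    """
    from .preprocess import average_replicates, detect_threshold, exclude_saturation, to_relative

    if config is None:
        config = GeneratorConfig(seed=seed, sigma_lambda=0.0)
    shots, truth = generate_study_dataset(config)
    segments = []
    for series in average_replicates(shots):
        E_th, lambda_th, _ = detect_threshold(series)
        segments.append(
            exclude_saturation(to_relative(series, E_th, lambda_th), saturation_factor)
        )
    data = CollapseDataset.from_segments(segments)
    if additive > 0 or multiplicative > 0:
        rng = np.random.default_rng(seed + 1)
        data = perturb_delta_lambda(data, rng, additive=additive, multiplicative=multiplicative)
    return data, truth


def perturb_delta_lambda(
    data: CollapseDataset,
    rng: np.random.Generator,
    additive: float = 0.0,
    multiplicative: float = 0.0,
) -> CollapseDataset:
    """Noisy copy of a collapse dataset.

    Applies multiplicative Gaussian noise (relative sigma) and/or additive
    Gaussian noise (nm) to ``delta_lambda_p``.  Points driven negative are
    dropped — mirroring the preprocessing rule that enforces non-negativity
    by exclusion rather than clamping.
    """
    dl = data.delta_lambda_p.copy()
    if multiplicative > 0:
        dl = dl * (1.0 + rng.normal(0.0, multiplicative, size=dl.size))
    if additive > 0:
        dl = dl + rng.normal(0.0, additive, size=dl.size)
    dl = np.where(data.delta_E == 0, 0.0, dl)  # threshold anchors stay exact
    keep = dl >= 0
    return CollapseDataset(
        sample_ids=data.sample_ids[keep],
        mu_s_prime=data.mu_s_prime[keep],
        mu_a=data.mu_a[keep],
        delta_E=data.delta_E[keep],
        delta_lambda_p=dl[keep],
    )
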