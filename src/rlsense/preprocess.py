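"""Turn raw random-laser peak measurements into lasing-regime coordinates.

The pipeline stage implemented here: replicate averaging, lasing-threshold
detection from the blueshift-to-redshift turning point of the peak
wavelength (with FWHM and peak-intensity cross-checks), conversion to
relative coordinates (dE, dlp) referenced to the threshold, and exclusion of
the gain-saturation regime far above threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    DomainError,
    FeatureError,
    InsufficientPointsError,
    NoLasingError,
)
from .model import OpticalProperties

__all__ = [
    "PeakSeries",
    "LasingSegment",
    "Spectrum",
    "ThresholdCrosschecks",
    "average_replicates",
    "extract_peak_features",
    "detect_threshold",
    "threshold_crosschecks",
    "to_relative",
    "exclude_saturation",
]

#: Minimum records a peak series needs: points on both sides of the threshold.
MIN_RECORDS = 5


@dataclass
class PeakSeries:
    """Replicate-averaged peak-wavelength response of one sample.

    ``E`` (mJ, strictly increasing), ``lambda_p`` (nm) and the optional
    ``fwhm`` (nm) / ``intensity`` (a.u.) channels are aligned arrays.
    """

    sample_id: str
    op: OpticalProperties
    E: np.ndarray
    lambda_p: np.ndarray
    fwhm: np.ndarray | None = None
    intensity: np.ndarray | None = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        self.lambda_p = np.asarray(self.lambda_p, dtype=float)
        if self.fwhm is not None:
            self.fwhm = np.asarray(self.fwhm, dtype=float)
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
        if self.E.size != self.lambda_p.size:
            raise DataError("E and lambda_p must have equal length")
        if self.E.size < MIN_RECORDS:
            raise DataError(
                f"peak series needs at least {MIN_RECORDS} records, got {self.E.size}"
            )
        if np.any(self.E <= 0):
            raise DataError("pump energies must be positive")
        if np.any(np.diff(self.E) <= 0):
            raise DataError("pump energies must be strictly increasing after averaging")


@dataclass
class LasingSegment:
    """Lasing-regime relative coordinates of one sample.

    ``delta_E = E - E_th`` and ``delta_lambda_p = lambda_p - lambda_th`` are
    both non-negative; the threshold record is the reference point (0, 0).
    """

    sample_id: str
    op: OpticalProperties
    E_th: float
    lambda_th: float
    delta_E: np.ndarray
    delta_lambda_p: np.ndarray

    def __post_init__(self) -> None:
        self.delta_E = np.asarray(self.delta_E, dtype=float)
        self.delta_lambda_p = np.asarray(self.delta_lambda_p, dtype=float)
        if self.delta_E.size != self.delta_lambda_p.size:
            raise DataError("delta_E and delta_lambda_p must have equal length")
        if np.any(self.delta_E < 0) or np.any(self.delta_lambda_p < 0):
            raise DataError("lasing segment coordinates must be non-negative")
        at_zero = self.delta_E == 0
        if np.any(self.delta_lambda_p[at_zero] != 0):
            raise DataError("delta_E = 0 must imply delta_lambda_p = 0")


@dataclass
class Spectrum:
    """A single emission spectrum: ascending wavelengths (nm), intensities (a.u.)."""

    wavelengths: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.size != self.intensities.size:
            raise DataError("wavelengths and intensities must have equal length")
        if self.wavelengths.size < 16:
            raise DataError("spectrum needs at least 16 samples")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise DataError("wavelengths must be strictly ascending")


@dataclass
class ThresholdCrosschecks:
    """Diagnostic threshold estimates from the monotone channels (mJ or None)."""

    E_th_fwhm: float | None = None
    E_th_intensity: float | None = None


def average_replicates(shots: pd.DataFrame) -> list[PeakSeries]:
    """Average per-shot records into one :class:`PeakSeries` per sample.

    ``shots`` is a tidy table with columns ``sample_id``, ``mu_s_prime``,
    ``mu_a``, ``pump_energy_mJ``, ``peak_wavelength_nm`` and optionally
    ``fwhm_nm`` / ``peak_intensity``.  Records are grouped by
    (sample, pump energy), the arithmetic mean is taken per group, and groups
    are sorted by energy.
    """
    if shots.empty:
        raise DataError("no shot records to average")
    required = {"sample_id", "mu_s_prime", "mu_a", "pump_energy_mJ", "peak_wavelength_nm"}
    missing = required - set(shots.columns)
    if missing:
        raise DataError(f"missing required columns: {sorted(missing)}")

    series: list[PeakSeries] = []
    for sample_id, grp in shots.groupby("sample_id", sort=True):
        op = OpticalProperties(
            mu_s_prime=float(grp["mu_s_prime"].iloc[0]),
            mu_a=float(grp["mu_a"].iloc[0]),
        )
        by_e = grp.groupby("pump_energy_mJ", sort=True)
        agg = by_e["peak_wavelength_nm"].mean()
        fwhm = by_e["fwhm_nm"].mean().to_numpy() if "fwhm_nm" in grp and grp["fwhm_nm"].notna().all() else None
        inten = (
            by_e["peak_intensity"].mean().to_numpy()
            if "peak_intensity" in grp and grp["peak_intensity"].notna().all()
            else None
        )
        n_rep = int(by_e.size().max())
        series.append(
            PeakSeries(
                sample_id=str(sample_id),
                op=op,
                E=agg.index.to_numpy(dtype=float),
                lambda_p=agg.to_numpy(dtype=float),
                fwhm=fwhm,
                intensity=inten,
                n_replicates=n_rep,
            )
        )
    return series


def extract_peak_features(spectrum: Spectrum) -> tuple[float, float, float]:
    """Locate the emission line in a spectrum.

    Returns ``(lambda_p, fwhm, peak_intensity)``: the wavelength of the
    global intensity maximum, the full width between the two half-maximum
    crossings (found by linear interpolation bracketing the peak), and the
    maximum intensity.  Raises :class:`FeatureError` when the spectrum is
    flat or the line is truncated by the window.
    """
    w, y = spectrum.wavelengths, spectrum.intensities
    if np.ptp(y) == 0:
        raise FeatureError("flat spectrum: no unique peak")
    i_max = int(np.argmax(y))
    peak = float(y[i_max])
    lambda_p = float(w[i_max])
    half = peak / 2.0

    def _cross(indices) -> float:
        # first index pair straddling the half maximum, walking away from peak
        for j, k in indices:
            if (y[j] - half) * (y[k] - half) <= 0 and y[j] != y[k]:
                t = (half - y[j]) / (y[k] - y[j])
                return float(w[j] + t * (w[k] - w[j]))
        raise FeatureError("peak truncated: no half-maximum crossing in window")

    left = _cross([(i, i + 1) for i in range(i_max - 1, -1, -1)])
    right = _cross([(i, i + 1) for i in range(i_max, y.size - 1)])
    return lambda_p, right - left, peak


def detect_threshold(series: PeakSeries, median_filter: bool = False) -> tuple[float, float, int]:
    """Locate the lasing threshold from the peak-wavelength turning point.

    The peak wavelength blueshifts with pump energy below threshold and
    redshifts above it, so the lasing threshold is the record at the global
    minimum of ``lambda_p``.  Ties are broken toward the lowest energy.  A
    monotone series (minimum at either end) means no turning point was probed
    and raises :class:`NoLasingError` rather than silently returning an
    endpoint.

    With ``median_filter=True`` a moving median of window 3 is applied before
    locating the minimum (for noisy data); the returned values are still the
    unfiltered record at the located index.
    """
    lam = series.lambda_p
    if median_filter:
        padded = np.pad(lam, 1, mode="edge")
        lam = np.median(np.lib.stride_tricks.sliding_window_view(padded, 3), axis=1)
    idx = int(np.argmin(lam))  # argmin takes the first minimum: lowest E on ties
    if idx == 0 or idx == lam.size - 1:
        raise NoLasingError(
            f"sample {series.sample_id}: peak wavelength has no interior minimum "
            "(no lasing threshold within the probed energy range)"
        )
    return float(series.E[idx]), float(series.lambda_p[idx]), idx


def threshold_crosschecks(series: PeakSeries) -> ThresholdCrosschecks:
    """Diagnostic threshold estimates from the FWHM and intensity channels.

    FWHM: first pump energy where the linewidth drops below half the
    non-lasing plateau (taken as the series maximum, reached at the lowest
    energies) — spectral narrowing at lasing onset.  Intensity: breakpoint
    of a continuous two-segment piecewise-linear fit of intensity vs. energy
    (slope kink at lasing onset).  Both are diagnostics only; the
    peak-wavelength turning point remains the reference.
    """
    checks = ThresholdCrosschecks()
    E = series.E
    if series.fwhm is not None:
        plateau = float(np.max(series.fwhm))
        below = np.nonzero(series.fwhm < 0.5 * plateau)[0]
        if below.size:
            checks.E_th_fwhm = float(E[below[0]])
    if series.intensity is not None and E.size >= 4:
        checks.E_th_intensity = _piecewise_breakpoint(E, series.intensity)
    return checks


def _piecewise_breakpoint(x: np.ndarray, y: np.ndarray) -> float:
    """Breakpoint of the best continuous two-segment linear fit (hinge scan)."""
    best_c, best_sse = None, np.inf
    for c in x[1:-1]:
        design = np.column_stack([np.ones_like(x), x, np.maximum(x - c, 0.0)])
        _, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        sse = float(res[0]) if res.size else float(
            np.sum((y - design @ np.linalg.lstsq(design, y, rcond=None)[0]) ** 2)
        )
        if rank == 3 and sse < best_sse:
            best_c, best_sse = float(c), sse
    if best_c is None:
        raise DataError("piecewise-linear breakpoint fit is degenerate")
    return best_c


def to_relative(series: PeakSeries, E_th: float, lambda_th: float) -> LasingSegment:
    """Convert a peak series to threshold-referenced lasing coordinates.

    Keeps records with ``E >= E_th`` and ``lambda_p >= lambda_th`` (noise
    dips below the threshold wavelength are dropped, not clamped) and emits
    ``(E - E_th, lambda_p - lambda_th)``; the threshold record maps to (0, 0).
    """
    mask = (series.E >= E_th) & (series.lambda_p >= lambda_th)
    if int(mask.sum()) < 3:
        raise InsufficientPointsError(
            f"sample {series.sample_id}: only {int(mask.sum())} lasing points survive, need 3"
        )
    return LasingSegment(
        sample_id=series.sample_id,
        op=series.op,
        E_th=float(E_th),
        lambda_th=float(lambda_th),
        delta_E=series.E[mask] - E_th,
        delta_lambda_p=series.lambda_p[mask] - lambda_th,
    )


def exclude_saturation(seg: LasingSegment, factor: float | None = 20.0) -> LasingSegment:
    """Drop points far above threshold where gain saturation breaks the model.

    Removes points whose absolute pump energy exceeds ``factor * E_th``.
    ``factor=None`` (or infinite) disables the cut.
    """
    if factor is None or not np.isfinite(factor):
        return seg
    if not factor > 1:
        raise DomainError(f"saturation factor must exceed 1, got {factor}")
    mask = (seg.delta_E + seg.E_th) <= factor * seg.E_th
    return LasingSegment(
        sample_id=seg.sample_id,
        op=seg.op,
        E_th=seg.E_th,
        lambda_th=seg.lambda_th,
        delta_E=seg.delta_E[mask],
        delta_lambda_p=seg.delta_lambda_p[mask],
    )
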