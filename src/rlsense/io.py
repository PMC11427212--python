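"""Readers and writers for the package's plain-text artifacts.

Peak tables and estimates travel as comma-separated UTF-8 text with a fixed
header; calibration results, lasing segments and generator ground truth are
JSON documents.  Spectra are two-column delimited text (wavelength nm,
intensity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibrate import CalibrationResult, GainCurve, OptimizationResult, ReconstructionScore
from .errors import DataError
from .invert import SensingEstimate
from .model import CalibratedModel, OpticalProperties
from .preprocess import LasingSegment, PeakSeries, Spectrum, average_replicates
from .synth import SampleTruth, SyntheticTruth

__all__ = [
    "PEAK_TABLE_COLUMNS",
    "ReadReport",
    "read_peak_table",
    "write_peak_table",
    "save_segments",
    "load_segments",
    "save_calibration",
    "load_calibration",
    "save_truth",
    "load_truth",
    "write_estimates",
    "read_spectrum",
    "write_spectrum",
]

#: Canonical peak-table header; optional columns may be empty but the header
#: names are fixed.
PEAK_TABLE_COLUMNS = [
    "sample_id",
    "il_percent",
    "ink_percent",
    "mu_s_prime",
    "mu_a",
    "replicate",
    "pump_energy_mJ",
    "peak_wavelength_nm",
    "fwhm_nm",
    "peak_intensity",
]
_REQUIRED = ["sample_id", "mu_s_prime", "mu_a", "replicate", "pump_energy_mJ", "peak_wavelength_nm"]
_NUMERIC = ["mu_s_prime", "mu_a", "replicate", "pump_energy_mJ", "peak_wavelength_nm"]


@dataclass
class ReadReport:
    """Per-file read diagnostics: 1-based line numbers of rejected rows."""

    n_rows: int = 0
    bad_lines: list[int] = field(default_factory=list)


def read_peak_table(path) -> tuple[list[PeakSeries], ReadReport]:
    """Read a peak-table CSV into replicate-averaged :class:`PeakSeries`.

    Malformed rows (non-numeric required fields) are collected in the report
    with their line numbers; the read continues as long as no more than
    max(1, 1%) of the rows are bad, otherwise a :class:`DataError` is raised.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty peak table") from None
    except OSError as exc:
        raise DataError(f"{path}: {exc}") from None
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise DataError(f"{path}: peak table has no data rows")

    for col in _NUMERIC:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("fwhm_nm", "peak_intensity"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")

    bad = df[_NUMERIC].isna().any(axis=1) | df["sample_id"].isna()
    report = ReadReport(
        n_rows=len(df), bad_lines=[int(i) + 2 for i in df.index[bad]]  # +2: header, 1-based
    )
    if bad.sum() > max(1, 0.01 * len(df)):
        raise DataError(
            f"{path}: {int(bad.sum())}/{len(df)} malformed rows (lines {report.bad_lines[:10]}...)"
        )
    return average_replicates(df[~bad]), report


def write_peak_table(shots: pd.DataFrame, path) -> None:
    """Write per-shot records as the canonical peak-table CSV.

    Energies and wavelengths are stored with 4 decimals; optional fields that
    are absent stay empty.
    """
    df = shots.copy()
    for col in PEAK_TABLE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[PEAK_TABLE_COLUMNS]
    df.to_csv(path, index=False, float_format="%.4f", encoding="utf-8")


# ---------------------------------------------------------------------------
# segments


def save_segments(segments: list[LasingSegment], path) -> None:
    doc = [
        {
            "sample_id": s.sample_id,
            "mu_s_prime": s.op.mu_s_prime,
            "mu_a": s.op.mu_a,
            "E_th": s.E_th,
            "lambda_th": s.lambda_th,
            "delta_E": list(map(float, s.delta_E)),
            "delta_lambda_p": list(map(float, s.delta_lambda_p)),
        }
        for s in segments
    ]
    Path(path).write_text(json.dumps({"software_version": __version__, "segments": doc}, indent=1))


def load_segments(path) -> list[LasingSegment]:
    doc = json.loads(Path(path).read_text())
    return [
        LasingSegment(
            sample_id=s["sample_id"],
            op=OpticalProperties(mu_s_prime=s["mu_s_prime"], mu_a=s["mu_a"]),
            E_th=s["E_th"],
            lambda_th=s["lambda_th"],
            delta_E=np.array(s["delta_E"]),
            delta_lambda_p=np.array(s["delta_lambda_p"]),
        )
        for s in doc["segments"]
    ]


# ---------------------------------------------------------------------------
# calibration artifact


def _curve_dict(c: GainCurve) -> dict:
    return {"a": c.a, "b": c.b, "c": c.c}


def save_calibration(result: CalibrationResult, path) -> None:
    """Serialize a calibration result (consumed by the inversion stage)."""
    doc = {
        "software_version": __version__,
        "seed": result.seed,
        "r": result.r,
        "b": result.b,
        "k": result.k,
        "n_excluded": result.n_excluded,
        "normalized_curve": _curve_dict(result.normalized_curve),
        "reconstruction_r2": result.reconstruction.average,
        "reconstruction_per_sample": result.reconstruction.per_sample,
        "per_scale_optima": [
            {
                "optimizer": o.optimizer,
                "k1_init": o.k1_init,
                "k2_init": o.k2_init,
                "k1": o.k1,
                "k2": o.k2,
                "r_squared": o.r_squared,
                "n_evals": o.n_evals,
                "seed": o.seed,
                "curve": _curve_dict(o.curve),
            }
            for o in result.per_scale_optima
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_calibration(path) -> CalibrationResult:
    doc = json.loads(Path(path).read_text())
    optima = [
        OptimizationResult(
            k1=o["k1"],
            k2=o["k2"],
            r_squared=o["r_squared"],
            objective=1.0 - o["r_squared"],
            optimizer=o["optimizer"],
            k1_init=o["k1_init"],
            k2_init=o["k2_init"],
            n_evals=o["n_evals"],
            curve=GainCurve(**o["curve"]),
            seed=o.get("seed"),
        )
        for o in doc["per_scale_optima"]
    ]
    return CalibrationResult(
        r=doc["r"],
        b=doc["b"],
        k=doc["k"],
        per_scale_optima=optima,
        normalized_curve=GainCurve(**doc["normalized_curve"]),
        k_per_point=np.array([]),
        n_excluded=doc["n_excluded"],
        reconstruction=ReconstructionScore(
            per_sample=doc["reconstruction_per_sample"], average=doc["reconstruction_r2"]
        ),
        seed=doc.get("seed"),
    )


# ---------------------------------------------------------------------------
# ground truth


def save_truth(truth: SyntheticTruth, path) -> None:
    doc = {
        "software_version": __version__,
        "seed": truth.seed,
        "sigma_lambda": truth.sigma_lambda,
        "truth_model": {"k": truth.truth_model.k, "r": truth.truth_model.r, "b": truth.truth_model.b},
        "samples": {
            sid: {
                "mu_s_prime": t.op.mu_s_prime,
                "mu_a": t.op.mu_a,
                "E_th": t.E_th,
                "lambda_th": t.lambda_th,
                "E_th_continuous": t.E_th_continuous,
            }
            for sid, t in truth.samples.items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_truth(path) -> SyntheticTruth:
    doc = json.loads(Path(path).read_text())
    samples = {
        sid: SampleTruth(
            sample_id=sid,
            op=OpticalProperties(mu_s_prime=t["mu_s_prime"], mu_a=t["mu_a"]),
            E_th=t["E_th"],
            lambda_th=t["lambda_th"],
            E_th_continuous=t["E_th_continuous"],
        )
        for sid, t in doc["samples"].items()
    }
    return SyntheticTruth(
        samples=samples,
        truth_model=CalibratedModel(**doc["truth_model"]),
        sigma_lambda=doc["sigma_lambda"],
        seed=doc["seed"],
    )


# ---------------------------------------------------------------------------
# estimates and spectra


def write_estimates(estimates: list[SensingEstimate], path) -> None:
    rows = [
        {
            "sample_id": e.sample_id,
            "L_hat": e.L_hat,
            "se": e.se,
            "n_points": e.n_points,
            "mu_a_hat": e.mu_a_hat,
            "mu_s_prime_hat": e.mu_s_prime_hat,
            "flags": ";".join(e.flags),
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def read_spectrum(path) -> Spectrum:
    """Read a two-column (wavelength nm, intensity) delimited text file."""
    arr = np.loadtxt(path, delimiter=None if _is_whitespace_delimited(path) else ",")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DataError(f"{path}: expected two columns (wavelength, intensity)")
    return Spectrum(wavelengths=arr[:, 0], intensities=arr[:, 1])


def _is_whitespace_delimited(path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return "," not in line
    raise DataError(f"{path}: empty spectrum file")


def write_spectrum(spectrum: Spectrum, path) -> None:
    np.savetxt(
        path,
        np.column_stack([spectrum.wavelengths, spectrum.intensities]),
        fmt="%.5f",
        header="wavelength_nm intensity",
    )
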