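"""Curve-collapse calibration of the DRS-RL sensing model.

All samples' lasing-regime shifts, once divided by the diffuse reflectance
Rd = mu_s'/(k1 + k2*mu_a), collapse onto a single exponential gain curve.
The geometry parameters (k1, k2) are found by minimizing 1 - R^2 of that
pooled exponential fit, with two optimizers (Nelder-Mead simplex and a
literal improvement-thresholded Metropolis-Hastings rule) started from three
initial scales.  Because the objective only depends on the ratio k2/k1 (the
amplitude of the fitted curve absorbs the common scale), optima from
different starts differ in magnitude but share the ratio; a through-origin
regression of k2 on k1 across optima extracts the slope r.  Normalizing the
collapsed ordinate and averaging per-point scaling factors then yields the
general factor k and the gain rate b of the final calibrated model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import DataError, DomainError, FitError
from .model import (
    CalibratedModel,
    GainCurve,
    OpticalProperties,
    forward_delta_lambda,
)

__all__ = [
    "CollapseDataset",
    "OptimizationResult",
    "ReconstructionScore",
    "CalibrationResult",
    "EPS_DELTA_LAMBDA",
    "REFERENCE_NM_OPTIMA",
    "REFERENCE_MH_OPTIMA",
    "fit_exponential",
    "collapse_objective",
    "optimize_nelder_mead",
    "optimize_metropolis_hastings",
    "fit_k_linearity",
    "normalize_and_refit",
    "compute_general_k",
    "reconstruct_and_score",
    "calibrate",
]

#: Floor on delta_lambda_p (nm) for per-point scaling factors; a tenth of the
#: 0.1 nm spectral-resolution class, and excludes the (0, 0) threshold anchor.
EPS_DELTA_LAMBDA = 0.01

#: Optimal (k1, k2) pairs reported in the literature for the original
#: fiber-probe geometry, one pair per initial scale {10, 1, 0.1}: Nelder-Mead
#: and Metropolis-Hastings rows.  Their through-origin slope is 0.36 cm.
REFERENCE_NM_OPTIMA = ((4.22, 1.52), (0.43, 0.15), (0.04, 0.02))
REFERENCE_MH_OPTIMA = ((8.17, 2.94), (0.54, 0.19), (0.14, 0.05))


@dataclass
class CollapseDataset:
    """Pooled lasing-regime points from all samples, ready for collapse.

    Parallel arrays: per-point sample id, optical properties and relative
    coordinates.  Needs at least two distinct optical-property combinations
    and eight points in total.
    """

    sample_ids: np.ndarray
    mu_s_prime: np.ndarray
    mu_a: np.ndarray
    delta_E: np.ndarray
    delta_lambda_p: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.mu_s_prime = np.asarray(self.mu_s_prime, dtype=float)
        self.mu_a = np.asarray(self.mu_a, dtype=float)
        self.delta_E = np.asarray(self.delta_E, dtype=float)
        self.delta_lambda_p = np.asarray(self.delta_lambda_p, dtype=float)
        n = self.delta_E.size
        if not (
            self.sample_ids.size == self.mu_s_prime.size == self.mu_a.size
            == self.delta_lambda_p.size == n
        ):
            raise DataError("collapse dataset arrays must have equal length")
        if n < 8:
            raise DataError(f"need at least 8 pooled points, got {n}")
        if np.unique(np.column_stack([self.mu_s_prime, self.mu_a]), axis=0).shape[0] < 2:
            raise DataError("need at least 2 distinct optical-property combinations")
        if np.any(self.delta_E < 0) or np.any(self.delta_lambda_p < 0):
            raise DataError("relative coordinates must be non-negative")

    @classmethod
    def from_segments(cls, segments) -> "CollapseDataset":
        """Pool a list of :class:`~rlsense.preprocess.LasingSegment` objects."""
        ids, msp, ma, de, dl = [], [], [], [], []
        for seg in segments:
            n = seg.delta_E.size
            ids.extend([seg.sample_id] * n)
            msp.extend([seg.op.mu_s_prime] * n)
            ma.extend([seg.op.mu_a] * n)
            de.extend(seg.delta_E)
            dl.extend(seg.delta_lambda_p)
        return cls(np.array(ids), np.array(msp), np.array(ma), np.array(de), np.array(dl))

    def __len__(self) -> int:
        return int(self.delta_E.size)


@dataclass
class OptimizationResult:
    """Outcome of one (k1, k2) collapse optimization run."""

    k1: float
    k2: float
    r_squared: float
    objective: float
    optimizer: str
    k1_init: float
    k2_init: float
    n_evals: int
    curve: GainCurve
    seed: int | None = None
    history: list[float] | None = None  # objective at each accepted point (MH)

    def __post_init__(self) -> None:
        if not (self.k1 > 0 and self.k2 > 0):
            raise DomainError("optimal k1, k2 must be positive")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise DomainError(f"r_squared out of [0, 1]: {self.r_squared}")

    @property
    def ratio(self) -> float:
        """k2/k1 — the only identifiable combination (cm)."""
        return self.k2 / self.k1


@dataclass
class ReconstructionScore:
    """Per-sample and average R^2 of forward-model reconstruction."""

    per_sample: dict[str, float]
    average: float


@dataclass
class CalibrationResult:
    """Full calibration output: slope r, gain rate b, general factor k."""

    r: float
    b: float
    k: float
    per_scale_optima: list[OptimizationResult]
    normalized_curve: GainCurve
    k_per_point: np.ndarray
    n_excluded: int
    reconstruction: ReconstructionScore
    seed: int | None = None

    @property
    def model(self) -> CalibratedModel:
        return CalibratedModel(k=self.k, r=self.r, b=self.b)

    @property
    def reconstruction_r2(self) -> float:
        return self.reconstruction.average


def fit_exponential(x, y) -> GainCurve:
    """Nonlinear least squares of ``y = -a*exp(-b*x) + c``.

    Initialization is deterministic: c0 = max(y), a0 = c0 - min(y), and b0
    from a log-linear regression of log(c0 + delta - y) against x over the
    lower half of the x range, followed by fixed jittered restarts on
    failure — repeated calls on identical data agree exactly.  A constant y
    leaves b unidentifiable and raises :class:`FitError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DataError("x and y must have equal length")
    if x.size < 4:
        raise DataError(f"need at least 4 points to fit, got {x.size}")
    if np.any(x < 0):
        raise DomainError("x (relative pump energy) must be non-negative")
    scale = max(abs(float(np.max(y))), 1.0)
    if np.ptp(y) < 1e-12 * scale:
        raise FitError("constant ordinate: gain rate b is unidentifiable")

    c0 = float(np.max(y))
    a0 = max(c0 - float(np.min(y)), 1e-6 * scale)
    delta = 1e-6 * max(abs(c0), 1.0)
    lower = x <= np.median(x)
    z = c0 + delta - y[lower]
    pos = z > 0
    if int(pos.sum()) >= 2 and np.ptp(x[lower][pos]) > 0:
        slope = np.polyfit(x[lower][pos], np.log(z[pos]), 1)[0]
        b0 = -float(slope)
    else:
        b0 = np.nan
    if not np.isfinite(b0) or b0 <= 0:
        b0 = 1.0 / max(float(np.mean(x)), 1e-12)

    def _f(xx, a, b, c):
        return -a * np.exp(-b * xx) + c

    best = None
    for jitter in (1.0, 0.5, 2.0):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    _f, x, y, p0=(a0 * jitter, b0 * jitter, c0), maxfev=20000
                )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        a, b, c = (float(v) for v in popt)
        if np.isfinite([a, b, c]).all() and b > 0:
            return GainCurve(a=a, b=b, c=c)
        best = popt
    raise FitError("exponential fit did not converge", best=best)


def _pooled_r_squared(y: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        raise DataError("zero total variance: R^2 undefined")
    return 1.0 - ss_res / ss_tot


def collapse_objective(
    k1: float, k2: float, data: CollapseDataset
) -> tuple[float, GainCurve | None]:
    """Collapse badness 1 - R^2 of the pooled exponential fit at (k1, k2).

    The collapsed ordinates ``dlp * (k1 + k2*mu_a) / mu_s'`` are rescaled by
    their maximum before fitting, which makes the objective exactly invariant
    under (k1, k2) -> (c*k1, c*k2); the returned curve is scaled back to the
    unnormalized ordinate.  Fit failures propagate as the worst objective 1.
    """
    if not (k1 > 0 and k2 > 0):
        raise DomainError(f"k1, k2 must be positive, got ({k1}, {k2})")
    y = data.delta_lambda_p * (k1 + k2 * data.mu_a) / data.mu_s_prime
    ymax = float(np.max(y))
    if ymax <= 0:
        return 1.0, None
    yn = y / ymax
    try:
        curve_n = fit_exponential(data.delta_E, yn)
    except FitError:
        return 1.0, None
    r2 = _pooled_r_squared(yn, curve_n.predict(data.delta_E))
    r2 = min(r2, 1.0)
    curve = GainCurve(a=curve_n.a * ymax, b=curve_n.b, c=curve_n.c * ymax)
    return 1.0 - r2, curve


def optimize_nelder_mead(
    data: CollapseDataset,
    k1_init: float,
    k2_init: float,
    xatol: float = 1e-8,
    fatol: float = 1e-14,
    maxiter: int = 4000,
) -> OptimizationResult:
    """Minimize the collapse objective with the Nelder-Mead simplex.

    Positivity of (k1, k2) is enforced by optimizing their logarithms.  The
    objective is flat along the ray direction, so different initial scales
    converge to different magnitudes with the same ratio and the same R^2.
    """
    if not (k1_init > 0 and k2_init > 0):
        raise DomainError("initial k1, k2 must be positive")
    state = {"n": 0, "best": None}

    def _obj(theta: np.ndarray) -> float:
        k1, k2 = np.exp(theta)
        val, curve = collapse_objective(float(k1), float(k2), data)
        state["n"] += 1
        if curve is not None and (state["best"] is None or val < state["best"][0]):
            state["best"] = (val, float(k1), float(k2), curve)
        return val

    res = optimize.minimize(
        _obj,
        np.log([k1_init, k2_init]),
        method="Nelder-Mead",
        options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter, "maxfev": maxiter},
    )
    if state["best"] is None:
        raise FitError("collapse objective never produced a valid fit")
    val, k1, k2, curve = state["best"]
    # prefer scipy's converged point when it matches the best recorded value
    if res.fun <= val + 1e-15:
        k1, k2 = (float(v) for v in np.exp(res.x))
        val, curve = collapse_objective(k1, k2, data)
    return OptimizationResult(
        k1=k1,
        k2=k2,
        r_squared=1.0 - val,
        objective=val,
        optimizer="nelder-mead",
        k1_init=k1_init,
        k2_init=k2_init,
        n_evals=state["n"],
        curve=curve,
    )


def optimize_metropolis_hastings(
    data: CollapseDataset,
    k1_init: float,
    k2_init: float,
    n_iter: int = 10_000,
    proposal_scale: float = 0.1,
    seed: int | None = None,
    literal_rule: bool = True,
    temperature: float = 1.0,
) -> OptimizationResult:
    """Random-walk search for (k1, k2) with a Metropolis-Hastings-style rule.

    At each step a proposal is drawn from a Gaussian centered at the current
    point with standard deviation ``proposal_scale`` times the current
    parameter values (scale-appropriate across initial scales), and a uniform
    deviate ``alpha`` in (0, 1) is drawn.  Under the default *literal* rule
    the proposal is accepted iff ``p(current) - p(proposal) >= alpha`` with
    ``p`` the collapse objective 1 - R^2 — an improvement-thresholded descent
    that can never accept a worsening move.  ``literal_rule=False`` switches
    to the standard Metropolis criterion
    ``alpha < exp((p(current) - p(proposal)) / temperature)``.

    The best point ever *evaluated* (including rejected proposals) is
    reported.  Fully reproducible from ``seed``.
    """
    if n_iter < 1:
        raise DomainError("n_iter must be at least 1")
    if seed is None:
        raise DomainError("a seed is mandatory for the stochastic optimizer")
    if not (k1_init > 0 and k2_init > 0):
        raise DomainError("initial k1, k2 must be positive")
    rng = np.random.default_rng(seed)

    cur = np.array([k1_init, k2_init], dtype=float)
    p_cur, curve_cur = collapse_objective(cur[0], cur[1], data)
    best = (p_cur, cur[0], cur[1], curve_cur)
    history = [p_cur]
    n_evals = 1
    for _ in range(n_iter):
        prop = cur + rng.normal(size=2) * proposal_scale * cur
        if prop[0] <= 0 or prop[1] <= 0:
            continue  # out-of-domain proposal: rejected without evaluation
        p_prop, curve_prop = collapse_objective(prop[0], prop[1], data)
        n_evals += 1
        if curve_prop is not None and p_prop < best[0]:
            best = (p_prop, float(prop[0]), float(prop[1]), curve_prop)
        alpha = rng.uniform()
        if literal_rule:
            accept = (p_cur - p_prop) >= alpha
        else:
            accept = alpha < np.exp((p_cur - p_prop) / temperature)
        if accept:
            cur, p_cur = prop, p_prop
            history.append(p_prop)
    val, k1, k2, curve = best
    if curve is None:
        raise FitError("collapse objective never produced a valid fit")
    return OptimizationResult(
        k1=k1,
        k2=k2,
        r_squared=1.0 - val,
        objective=val,
        optimizer="metropolis-hastings" if literal_rule else "metropolis-hastings-standard",
        k1_init=k1_init,
        k2_init=k2_init,
        n_evals=n_evals,
        curve=curve,
        seed=seed,
        history=history,
    )


def fit_k_linearity(optima) -> float:
    """Through-origin least-squares slope r = sum(k1*k2) / sum(k1^2).

    ``optima`` is a sequence of (k1, k2) pairs or
    :class:`OptimizationResult` objects.  The through-origin form follows the
    proportionality k2 = r * k1 revealed across optimization runs.
    """
    pairs = [
        (o.k1, o.k2) if isinstance(o, OptimizationResult) else (float(o[0]), float(o[1]))
        for o in optima
    ]
    if len(pairs) < 1:
        raise DataError("need at least one (k1, k2) optimum")
    k1 = np.array([p[0] for p in pairs])
    k2 = np.array([p[1] for p in pairs])
    denom = float(np.sum(k1**2))
    if denom == 0:
        raise DomainError("all k1 are zero: slope undefined")
    return float(np.sum(k1 * k2) / denom)


def normalize_and_refit(
    data: CollapseDataset, k1: float, k2: float
) -> tuple[GainCurve, float]:
    """Refit the gain curve on ordinates normalized to their dataset maximum.

    Returns the normalized curve (maximum ordinate exactly 1) and the gain
    rate b, which is invariant to the normalization.
    """
    y = data.delta_lambda_p * (k1 + k2 * data.mu_a) / data.mu_s_prime
    ymax = float(np.max(y))
    if ymax <= 0:
        raise DataError("maximum collapsed ordinate is zero: cannot normalize")
    curve = fit_exponential(data.delta_E, y / ymax)
    return curve, curve.b


def compute_general_k(
    data: CollapseDataset, r: float, b: float, eps: float = EPS_DELTA_LAMBDA
) -> tuple[float, np.ndarray, int]:
    """General scaling factor k as the mean of per-point values.

    For each point with ``delta_lambda_p > eps``,
    ``k_i = (1 - exp(-b*dE_i)) * mu_s'_i / (dlp_i * (1 + r*mu_a_i))``; points
    at or below the floor (including the (0, 0) threshold anchors) are
    excluded and counted.  Returns ``(k, k_per_point, n_excluded)``.
    """
    if not (r > 0 and b > 0):
        raise DomainError("r and b must be positive")
    mask = data.delta_lambda_p > eps
    n_excluded = int((~mask).sum())
    if not mask.any():
        raise DataError("no points above the delta_lambda_p floor")
    k_per_point = (
        (1.0 - np.exp(-b * data.delta_E[mask]))
        * data.mu_s_prime[mask]
        / (data.delta_lambda_p[mask] * (1.0 + r * data.mu_a[mask]))
    )
    return float(np.mean(k_per_point)), k_per_point, n_excluded


def reconstruct_and_score(data: CollapseDataset, model: CalibratedModel) -> ReconstructionScore:
    """Score the calibrated model by reconstructing every sample's shifts.

    Predicts ``delta_lambda_p`` from the forward model for every point and
    computes R^2 per sample against the measured values; the average across
    samples is the headline reconstruction score.
    """
    per_sample: dict[str, float] = {}
    for sid in np.unique(data.sample_ids):
        mask = data.sample_ids == sid
        op = OpticalProperties(
            mu_s_prime=float(data.mu_s_prime[mask][0]), mu_a=float(data.mu_a[mask][0])
        )
        pred = forward_delta_lambda(op, data.delta_E[mask], model)
        per_sample[str(sid)] = _pooled_r_squared(data.delta_lambda_p[mask], pred)
    return ReconstructionScore(per_sample=per_sample, average=float(np.mean(list(per_sample.values()))))


def calibrate(
    data: CollapseDataset,
    init_scales=(10.0, 1.0, 0.1),
    optimizer: str = "nelder-mead",
    mh_iters: int = 10_000,
    seed: int | None = None,
) -> CalibrationResult:
    """Run the full collapse calibration and return the calibrated model.

    One optimization per initial scale (k1_init = k2_init = scale), the
    through-origin slope r across the per-scale optima, the normalized gain
    curve and rate b at the best optimum, the general factor k from per-point
    averaging, and the reconstruction score of the resulting model.
    """
    if optimizer not in ("nelder-mead", "metropolis-hastings"):
        raise DomainError(f"unknown optimizer {optimizer!r}")
    optima: list[OptimizationResult] = []
    for i, scale in enumerate(init_scales):
        if optimizer == "nelder-mead":
            optima.append(optimize_nelder_mead(data, scale, scale))
        else:
            if seed is None:
                raise DomainError("metropolis-hastings calibration requires a seed")
            optima.append(
                optimize_metropolis_hastings(
                    data, scale, scale, n_iter=mh_iters, seed=seed + i
                )
            )
    r = fit_k_linearity(optima)
    best = min(optima, key=lambda o: o.objective)
    normalized_curve, b = normalize_and_refit(data, best.k1, best.k2)
    k, k_per_point, n_excluded = compute_general_k(data, r, b)
    recon = reconstruct_and_score(data, CalibratedModel(k=k, r=r, b=b))
    return CalibrationResult(
        r=r,
        b=b,
        k=k,
        per_scale_optima=optima,
        normalized_curve=normalized_curve,
        k_per_point=k_per_point,
        n_excluded=n_excluded,
        reconstruction=recon,
        seed=seed,
    )
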