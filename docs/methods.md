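# Methods

## The sensing model

A random laser (RL) pumped in a turbid gain medium and observed in the
backscattered direction behaves, to a good approximation, like diffuse
reflectance with gain: multiple scattering provides the optical feedback, so
the emission carries the medium's optical properties the same way a diffuse
reflectance signal does, while the pump energy drives a gain effect that is a
property of the dye alone.

The diffuse reflectance of a semi-infinite turbid medium probed with a fiber
geometry is taken in the Zonios form

```
Rd = μs′ / (k₁ + k₂·μa)
```

with reduced scattering coefficient μs′ (cm⁻¹), absorption coefficient μa
(cm⁻¹), and geometry scaling parameters k₁ (dimensionless) and k₂ (cm, so
that k₂·μa is dimensionless).  The lasing-regime peak-wavelength shift
Δλp = λp − λth, referenced to its value at the lasing threshold, is assumed to
factorize as Δλp = Rd · f(ΔE) with ΔE = E − Eth the pump energy above
threshold.  The gain factor f is an exponential saturation (measured on the
transparent dye), so the collapsed ordinate obeys

```
Δλp · (k₁ + k₂·μa) / μs′ = −a·e^(−b·ΔE) + c
```

and, after calibration, the model condenses to

```
k · Δλp · (1 + r·μa) / μs′ = 1 − e^(−b·ΔE)
```

with a single general scaling factor k (dimensionless), the
absorption-to-scattering slope r = k₂/k₁ (cm) and the gain rate b (mJ⁻¹).
The package's reference calibration for the original fiber-probe geometry is
k = 9.59, r = 0.36 cm, b = 0.034 mJ⁻¹ (`rlsense.REFERENCE_MODEL`), and the
synthetic generator uses it as ground truth.

Units everywhere: energies mJ, wavelengths nm, optical coefficients cm⁻¹.
k₂ and r carry cm so their products with μa are dimensionless; no conversion
layer exists.

Assumptions worth stating plainly:

- μs′ is treated as wavelength-independent per sample (an average over the
  peak-wavelength range).
- The model covers only the lasing regime, ΔE ≥ 0; negative relative energies
  are rejected, not extrapolated.
- Gain saturation far above threshold is *outside* the model; points with
  absolute pump energy above 20·Eth are excluded before calibration
  (configurable, disabled with `factor=None`).
- The phase function / anisotropy dependence of Rd is not modeled.

## Preprocessing

Raw data are per-shot peak records (five replicates per pump energy by
default).  Replicates are averaged arithmetically per (sample, energy).  The
lasing threshold is the blueshift-to-redshift turning point of λp(E): the
record at the global minimum of λp, ties broken toward the lowest energy.  A
monotone series raises a "no lasing" error rather than silently returning an
endpoint.  Threshold detection runs on averaged, unsmoothed data; a window-3
moving median is available behind a flag for noisy series.

Relative coordinates keep only records with E ≥ Eth and λp ≥ λth; points
driven below λth by noise are dropped, not clamped, because clamping would
bias the exponential fit near the origin.  At least 3 points must survive.

Two diagnostic threshold cross-checks are computed when the channels are
present — first energy where the FWHM falls below half its non-lasing plateau
(taken as the series maximum), and the breakpoint of a continuous two-segment
piecewise-linear fit of intensity vs. energy.  Their constants are package
inventions; they never feed calibration.

## Calibration

`collapse_objective(k1, k2, data)` pools every sample's (ΔE, Δλp/Rd) points,
fits the exponential by nonlinear least squares, and returns 1 − R² of the
pooled fit.  Numerical choices:

- The exponential fit is initialized deterministically: c₀ = max(y),
  a₀ = c₀ − min(y), b₀ from a log-linear regression of log(c₀ + δ − y) on the
  lower half of the x range (δ = 10⁻⁶·max(|c₀|, 1)), with two fixed jittered
  restarts.  Identical inputs give identical fits.  A constant ordinate makes
  b unidentifiable and is an error, not a silent boundary fit.
- Collapsed ordinates are rescaled by their maximum before fitting.  R² is
  scale-invariant, so this changes nothing statistically, but it makes the
  ray degeneracy objective(c·k₁, c·k₂) = objective(k₁, k₂) *exact by
  construction* rather than approximate at optimizer tolerance.
- R² is computed on the pooled cloud (all samples together), since one curve
  is fitted to the merged data.

Only the ratio k₂/k₁ is identifiable — the curve amplitude absorbs the common
scale.  Optimization therefore runs from three initial scales (10, 1, 0.1;
k₁init = k₂init) and the slope r is the through-origin least-squares slope
Σk₁k₂/Σk₁² across the per-scale optima.  A free intercept is not supported by
the proportionality k₂ = r·k₁.  Two optimizers are provided:

- **Nelder-Mead** simplex on (log k₁, log k₂) (positivity by
  reparameterization).
- **Metropolis-Hastings, literal rule** (default): proposals are Gaussian
  with σ = 10% of the current parameter per coordinate; a proposal is
  accepted iff p(current) − p(proposal) ≥ α with α ~ Uniform(0,1).  This rule
  only ever accepts improvements, with probability equal to the improvement —
  it is an improvement-thresholded descent, not a sampler — so the best point
  ever *evaluated* (including rejected proposals) is reported.  A standard
  Metropolis criterion (accept with probability min(1, e^((p−p′)/T))) sits
  behind `literal_rule=False` for diagnostics.  Seeds are mandatory; runs are
  bit-reproducible.

After optimization the collapsed ordinates are normalized to their maximum
and refitted (the rate b is invariant to this), and the general factor k is
the arithmetic mean of per-point values
kᵢ = (1 − e^(−b·ΔEᵢ))·μs′ᵢ / (Δλpᵢ·(1 + r·μaᵢ)), excluding points with
Δλp ≤ 0.01 nm (a tenth of the 0.1 nm spectral-resolution class; this also
removes the (0, 0) threshold anchors from the division).  The calibrated
model is scored by per-sample R² of the reconstructed Δλp, averaged across
samples.

## Inversion and identifiability

One sample's lasing series determines only the lump L = μs′/(1 + r·μa), the
through-origin slope of Δλp against (1 − e^(−b·ΔE))/k.  Recovering μa
requires a known μs′ (μa = (μs′/L − 1)/r) and vice versa
(μs′ = L·(1 + r·μa)); the package makes this conditional recovery explicit
instead of claiming joint recovery from one series.  A negative recovered μa
(inputs outside the model domain) is flagged, never clipped.  The regression
is through the origin because the model forces Δλp = 0 at ΔE = 0.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *measurement structure* of the Intralipid/ink
phantom study: 2 Intralipid levels (μs′ = 63.78 and 106.13 cm⁻¹, linear
interpolation between these anchors for intermediate concentrations, since
they are not proportional through the origin), ink μa from 0 to 8.64 cm⁻¹
(proportional, 96·ink%), a 2×5 OP grid by default, pump energies 1.82–40.86
mJ on a half-Gaussian grid (half-normal quantiles affinely rescaled so both
endpoints are exact and sampling is denser at low energy), and 5 replicates
with additive per-shot wavelength noise (default σ = 0.05 nm).

Above threshold the peak wavelength follows the calibrated forward model
exactly (optionally damped by a saturation factor 1 − s·ΔE/(ΔE + E_sat),
default off, used only for qualitative deviation tests).  The threshold model
E_th = E₀·(1 + r·μa)·(μs′_ref/μs′) and the below-threshold blueshift
λp = λth + depth·(1 − E/Eth)^exp are *inventions* constrained only by the
qualitative phenomenology (absorption raises the threshold and blueshifts;
scattering does the opposite); their constants (E₀ = 4 mJ reference
threshold, depth 1.5 nm, λ₀ = 565 nm — a plausible R6G lasing wavelength
whose absolute value nothing depends on) live in `GeneratorConfig` and are
stored in the truth record.  Thresholds are snapped to the nearest interior
grid energy so the turning point is exactly probeable.  The FWHM (30 nm →
0.3 nm logistic collapse) and intensity (slope kink) channels are
deterministic diagnostics.

Consequently, passing recovery tests show that the *pipeline* is correct and
well-conditioned under the study's sampling structure and noise scale.  They
do not validate the physical model against real random-laser data: real
below-threshold behavior, mode competition, pump jitter and instrument
response are not simulated.

## Problem sizes and defaults

The standard test/calibration dataset is the 2×5 OP grid × 30 energies
(≈ 220 pooled lasing points after preprocessing), chosen to match the study's
sampling density; Monte-Carlo checks use 200–500 replicates of 20-point
segments.  Nelder-Mead uses xatol 1e-8 / fatol 1e-14 in log-space; MH
defaults to 10,000 iterations.  All stochastic stages require explicit seeds
and are reproducible bit-for-bit.

## Known limitations

- Absolute (k₁, k₂) magnitudes are not identifiable from collapse; only the
  ratio is meaningful.  Reported per-scale optima reproduce this honestly.
- The literal MH rule freezes near an optimum (acceptance probability equals
  the improvement); its usefulness comes from reporting the best evaluated
  point, and its results should be cross-checked against Nelder-Mead (the
  package does this in its tests).
- The mean-of-ratios estimator for k is noise-biased upward at second order
  (E[1/(1+ε)] ≈ 1 + σ²); at the 1–2% noise of interest the bias is ≪ 1%.
- Physical derivation of optical properties from raw concentrations is out of
  scope; only the anchored interpolation used by the generator is provided.
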