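# rlsense

Quantitative sensing of optical properties in turbid media from random-laser
emission, combining the diffuse-reflectance picture of light transport with
the exponential gain response of the dye.

**Who it is for.** Biophotonics groups characterizing absorption (μa) and
reduced scattering (μs′) of tissue-like phantoms or tissue with a
random-laser probe, and anyone studying the peak-wavelength shift of random
lasers as a sensing parameter.

## The model

A random laser observed in backscatter behaves like diffuse reflectance with
gain.  With the Zonios reflectance `Rd = μs′/(k₁ + k₂·μa)` and a universal
exponential gain effect, the lasing-regime peak-wavelength shift
Δλp = λp − λth (referenced to the lasing threshold, where λp turns from
blueshift to redshift) obeys

```
k · Δλp · (1 + r·μa) / μs′ = 1 − e^(−b·ΔE),      ΔE = E − Eth
```

with a general scaling factor k, slope r = k₂/k₁ (cm) and gain rate b
(mJ⁻¹).  The package

- simulates realistic peak-series measurements with stored ground truth
  (`rlsense.synth`),
- detects lasing thresholds and builds relative coordinates
  (`rlsense.preprocess`),
- calibrates (k₁, k₂) by curve-collapse optimization — minimizing 1 − R² of
  the pooled exponential fit with Nelder-Mead and a Metropolis-Hastings-style
  rule from three initial scales — and extracts (k, r, b)
  (`rlsense.calibrate`),
- inverts the calibrated model for the identifiable lump
  L = μs′/(1 + r·μa) and, given one known coefficient, the other
  (`rlsense.invert`).

See `docs/methods.md` for the model's assumptions, numerical choices and
limitations.

## Worked example

```sh
rlsense simulate   --seed 42 --out peaks.csv --truth truth.json --sigma-lambda 0.02
rlsense preprocess --in peaks.csv --out segments.json
rlsense calibrate  --in segments.json --out calibration.json
rlsense invert     --in segments.json --calibration calibration.json --out estimates.csv
```

The calibrate stage prints (this exact output, since every stage is seeded):

```
per-scale optima (init -> optimal k1, k2, R^2):
  nelder-mead            init (10, 10) -> k1=16.78, k2=6.061, R^2=0.999736 [139 evals]
  nelder-mead            init (1, 1) -> k1=1.593, k2=0.5755, R^2=0.999736 [147 evals]
  nelder-mead            init (0.1, 0.1) -> k1=0.165, k2=0.0596, R^2=0.999736 [139 evals]
slope r = k2/k1 : 0.3613 cm
gain rate b     : 0.03371 1/mJ
general factor k: 9.5846  (10 points below floor excluded)
reconstruction R^2 (sample average): 0.9996
```

Reading this: the optimal (k₁, k₂) magnitudes differ wildly across initial
scales — only their ratio is identifiable, and the collapse R² is the same
for all of them — but all optima line up on one ray, whose through-origin
slope is r ≈ 0.36 cm.  The recovered gain rate b ≈ 0.034 mJ⁻¹ and general
factor k ≈ 9.59 match the generator's ground truth (the reference
calibration `rlsense.REFERENCE_MODEL`), and the calibrated model reconstructs
every sample's shifts with average R² ≈ 1.

The invert stage then reports, per sample, the lump L = μs′/(1 + r·μa) with
its standard error and — since the phantom's μs′ is known — the recovered
absorption, e.g. `IL5_ink0.0225: L = 35.98 ± 0.04 cm⁻¹, μa_hat = 2.14 cm⁻¹`
(truth 2.16).  For the ink-free sample the noisy estimate comes out slightly
negative (−0.015 cm⁻¹) and is flagged `mu_a_outside_model_domain` rather than
clipped.

`rlsense reference-linearity` prints the through-origin slope of the
published per-scale optima for the original probe geometry (0.36 for both
optimizers).

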