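# Methods

## The problem

A trackway — a sequence of footprints, here imprinted in snow — preserves one
usable kinematic quantity: the stride length `l_stride`, the distance between
successive placements of the same foot. The question this package addresses
is how much locomotor information (speed, gait) can be recovered from
`l_stride` alone, and with what error, for a bipedal trackmaker whose ground
truth is known. The model system is the Svalbard rock ptarmigan
(*Lagopus muta hyperborea*), a bird for which matched trackway photographs
and simultaneous video-derived speeds exist, together with a literature
functional hip height of `h = 0.1727 m`.

## Models

### Dimensionless numbers

The Froude number `Fr = U² / (g h)` equalises the centripetal-to-
gravitational force ratio; geometrically similar animals moving at equal `Fr`
move in a dynamically similar way, which is what licenses borrowing
empirical speed–stride relations across body sizes. The relative stride
length `λ = l_stride / h` is the dimensionless stride used for gait
diagnosis.

### General (Froude-based) predictors

Two classical closed-form predictors are implemented with their published
constants (these are fixed constants of the named models, not fitting
parameters):

* walking predictor: `U = 0.25 g^0.5 l_stride^1.67 h^−1.17`;
* fast-gait predictor: `U = [g h (l_stride / 1.8 h)^2.56]^0.5`.

For the intermediate (trotting) band the recommended estimate is the
arithmetic mean of the two. The piecewise dispatcher applies the literature
band boundaries `λ = 2.0` (walk → trot) and `λ = 2.9` (trot → run). Two
consequences of these forms are used as internal consistency checks: at
`l = 1.8 h` the fast-gait predictor reduces exactly to `sqrt(g h)`, and
substituting `l = 2 h` into the walking predictor yields an implied
`Fr = (0.25·2^1.67)² ≈ 0.63` independent of `h` (the exponents satisfy
`1.67 − 1.17 = 0.5`, so `h` cancels) — matching the classical transition
pair (`Fr ≈ 0.6`, `λ = 2.0`).

Band boundaries are half-open with the boundary point going to the *faster*
gait: once `λ` reaches 2.0 the gait has shifted. The piecewise model is
deliberately discontinuous at the boundaries; no smoothing is applied,
because the published recipe is piecewise and a smoothed hybrid would be a
different model. `g` defaults to 9.81 m/s² (conventional value; it
reproduces the worked `Fr = 0.5` check for the fastest walker).

Hip height, when the animal is unavailable, is proxied as 4× footprint
length (`hip_from_footlength`). Postural uncertainty makes such proxies
uncertain by a factor of ~1.5, and every predictor scales with a negative
power of `h`, so this is typically the dominant error source for extinct
trackmakers.

### Species-specific calibration

For a species with matched (stride, speed) data, speed is regressed on
stride length by ordinary least squares **separately per gait** (walking,
grounded running, aerial running) — the slope of speed on stride differs
between gaits, so pooling would bias all three. The fit is delegated to
statsmodels OLS; the stored model keeps slope, intercept, `n`, residual SD
(`sqrt(SSR/(n−2))`), `r²`, the F statistic with df `(1, n−2)`, the observed
stride range, and the sufficient statistics (`l̄`, `Sxx`) for intervals.
Records without a measured speed are excluded with a logged count; no
weighting by the number of strides averaged per trackway is applied (no
weights are justified by the data model).

Prediction intervals are the two-sided t intervals for a *single new
observation*: half-width `t_{1−α/2, n−2} · s · sqrt(1 + 1/n + (l − l̄)²/Sxx)`.
The default level is 95% and is configurable. Residual normality — the
assumption behind the t intervals — is checked by a Shapiro–Wilk test on
the fit residuals.

Degenerate inputs: fewer than three usable records raises
`InsufficientDataError`; zero predictor variance raises
`DegenerateDesignError`; an exactly linear dataset has its floating-noise
residual SD snapped to 0 (threshold `1e−12` relative to the response
scale), which collapses the prediction interval to the point, and makes the
Shapiro–Wilk statistic undefined (raised as degenerate).

### Gait classification and ambiguity

Two schemes:

* **relative_stride** — the literature bands on `λ` (defaults 2.0, 2.9,
  configurable, must be increasing). Always a single call, never ambiguous.
* **species_ranges** — a gait matches when the trackway's stride falls
  inside that gait's *observed training stride range* (inclusive at both
  ends). Real gaits overlap in stride length around the transitions, so a
  stride can match two gaits: such calls are flagged ambiguous, and the
  `unclassifiable_fraction` of a cohort is the mean of those flags. A
  stride outside every range reports the nearest gait with an
  `out_of_range` flag — never silently clamped.

The default species-range mode uses stride ranges rather than speed
intervals because the scientific question is what can be inferred "from
stride length alone". An alternative `speed_interval` mode is available
behind a flag: a gait matches when the t prediction interval at `l` under
that gait's model intersects the gait's fitted speed range over its
observed strides — a looser, speed-space notion of compatibility. The
choice of interpretation is genuinely open; the stride-range default is
documented as the package's reading.

### Error analysis

Signed percent error is `100 (predicted − measured)/measured`; negative
values are underestimates. The printed form of the error equation is a
fraction; reported values are percentages, so the ×100 is applied at
output. Summaries report the mean of *absolute* errors as the headline
accuracy figure (error distributions span both signs, so a signed mean
understates inaccuracy through cancellation) alongside the signed mean
(bias), both SDs (population form, `ddof=0`), the signed extremes, and a
histogram with width-10 bins anchored at multiples of 10 percent,
closed-left/open-right.

## The synthetic-data generator

The generator emulates the structure of the field campaign: for each gait,
`n` stride lengths drawn from a distribution over the gait's stride range,
ground-truth speed `u = slope·l + intercept + N(0, residual_sd)`, and an
optional Gaussian perturbation of the *recorded* stride to mimic
photograph-measurement error (the video measures speed independently of
the photograph, so speed is computed from the true stride). Draws that
would make a speed or recorded stride non-positive are redrawn; at the
default noise levels this truncation is ~5 SD from zero and negligible.

Defaults are the study conditions of the ptarmigan system:

| gait             | slope (m/s)/m | intercept m/s | residual SD m/s | stride range m | n  |
|------------------|---------------|---------------|-----------------|----------------|----|
| walking          | 3.20          | −0.23         | 0.092           | 0.225–0.322    | 48 |
| grounded running | 2.34          | +0.34         | 0.168           | 0.312–0.436    | 56 |
| aerial running   | 4.29          | −0.03         | 0.180           | 0.373–0.646    | 61 |

Stride ranges invert the published predicted-speed endpoints
(0.49–0.80, 1.07–1.36, 1.57–2.74 m/s) through each gait's equation, and are
verified by forward substitution. Residual SDs are back-calculated as
prediction-interval half-widths (±0.18, ±0.33, ±0.34…0.37 m/s) divided by
1.96 — an acknowledged approximation, since a prediction-interval
half-width also carries fit uncertainty and therefore slightly exceeds the
residual SD. Stride lengths default to uniform over the range (the least
assumption absent any published stride distribution; a mid-range truncated
normal is available). The hold-out generator draws 50 trackways with gait
counts multinomial in proportion 48:56:61, all carrying ground truth.

Randomness flows through a single splittable seed (`numpy SeedSequence`),
one child stream per gait, so adding a gait never reshuffles the draws of
the others; identical (specs, seed) pairs produce byte-identical CSV.

What the generator does **not** emulate: snow compliance and footprint
formation, sex and ontogeny structure, the true joint stride distribution,
or any within-trackway correlation. Tests passing on synthetic cohorts
therefore validate the statistical machinery and its calibration behaviour
under the assumed linear-Gaussian data model — not the field accuracy of
the predictors on real snow trackways, which depends on exactly the
substrate effects the generator omits.

## Numerical and design choices

* OLS via statsmodels; an independent normal-equation solver serves as the
  oracle in tests, keeping the implementation and its check on separate
  code paths.
* Prediction-interval coverage is validated *unconditionally*: ~200
  replicate fits × 10 new observations each, since coverage conditional on
  a single fit is itself random.
* Problem sizes in tests and the acceptance script (500 replicate fits per
  gait, 2000 coverage draws, study-scale cohorts of 165 + 50) were chosen
  so the Monte-Carlo standard error of each checked quantity is well inside
  its assertion tolerance (e.g. slope-recovery MC SE ≈ 0.001–0.03 against
  ±0.05 bands) while the whole suite runs in seconds.
* Gait labels are a controlled vocabulary (`walking`, `grounded_running`,
  `aerial_running`); `trot` is accepted on input and normalised to
  `grounded_running` with a logged note, because the general models' trot
  band maps onto the ptarmigan's grounded run when the two families of
  models are compared.
* Units are fixed SI (m, m/s); no unit auto-detection, by design — silent
  conversion is a classic source of wrong speeds.

## Known limitations

* The per-gait regressions treat trackways as independent observations;
  there is no mixed-effects structure for repeated individuals.
* Classification is threshold/range-based, not probabilistic; no posterior
  gait probabilities are produced.
* Stride-length measurement error on real photographed trackways is not
  modelled in the analysis path (the generator exposes a knob for it, so
  its effect on calibration can be explored synthetically).
* The species-calibrated model transfers to no other species; the general
  predictors transfer but inherit hip-height proxy error.
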