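# Methods

This document records the model equations, default parameters, numerical
choices and known limitations of `lumitint`.

## 1. Display calibration

**Response model.** The display's optical response is modelled as a rational
function of the 8-bit grey value `g`:

```
f(g) = (a·g² + b·g + c) / (g² + d·g + e)   [log₁₀ optical power, μW]
```

The in-package preset (`reference_curve()`) uses the characterized
coefficients `a=7.04, b=1706, c=−63550, d=1274, e=30270`. Luminance is
proportional to power with `lum_per_uw = 140/93 cd/m²/μW`, anchoring full
drive (grey 255, 93 μW) at 140 cd/m².

**Fitting.** `fit_response` averages photometer repeats in linear power per
grey, then fits log₁₀ mean power:

- *Initialisation:* Sanathanan–Koerner iterations of the classical
  linearisation `y·(g²+dg+e) = a·g²+bg+c`, each pass reweighted by the
  previous denominator. The plain one-shot linearised solve is strongly
  biased by the very noisy low-grey measurements and can place a denominator
  pole inside the grey range; the reweighted iterations remove that bias.
- *Refinement:* Levenberg–Marquardt on the true residual with the
  denominator parameterised as `(g+p)(g+q)`, `p,q = exp(·) > 0`, which
  structurally excludes poles on `g ≥ 0`. The result is validated (positive
  denominator, strictly increasing response) before use.

At the reference noise levels the fit recovers the true response within
≈ 0.01 log₁₀ units over greys 17–255.

**Linearization LUT.** Greys below 10 are unusable (luminance collapses and
measurement noise explodes), so the usable range is greys 10–255, spanning
log₁₀ luminance −0.85 … 2.15 (three magnitudes, 0.14–140 cd/m²). The LUT
assigns each input grey a target on the straight line through those
endpoints and maps it to the output grey whose fitted luminance is nearest
(nearest neighbour in linear luminance, ties to the lower grey); greys 0–9
clamp to the grey-10 mapping. The residual between realized and target log
luminance is below half a local quantization step everywhere.

## 2. Lens model

**Static lenses.** Clear lens T = 0.95, sunglasses T = 0.20.

**Self-tinting kinetics.** Transmission moves between `t_max = 0.9` and
`t_min = 0.1` exponentially:

```
clear → dark:  T(t) = (t_max − t_min)·e^(−k·t) + t_min
dark → clear:  mirrored about (t_max + t_min)/2
```

with `k = 2.073 /s` (fast) or `0.691 /s` (slow). The 90 %-completion
response time is `ln(10)/k`: ≈ 1.11 s → 1 s fast, ≈ 3.33 s → 3 s slow.

**Sensor trigger.** An ambient-light sensor switches the lens when luminance
crosses 4 cd/m² (downward → lighten, upward → darken) with a 100 ms
processing delay. The crossing time is interpolated linearly in log₁₀
luminance between frames, which is exact for the protocol's log-linear
ramps.

**Alpha compositing.** A lens of transmission T over a wall of grey `g` and
luminance `L` is emulated by the overlay opacity
`α = 1 − g_behind/g`, where `g_behind` is the inverse-lookup grey of `T·L`.
`alpha_from_transmission` takes the wall luminance as an argument; the
protocol passes the *commanded* luminance (140 or 0.14 cd/m²). This matters:
the fitted luminance of grey 255 (≈ 141.7 cd/m²) differs from the measured
140 cd/m² by ≈ 1.2 %, and only the commanded value reproduces the published
behind-lens grey 151 for T = 0.30 (α = 0.408).

## 3. Trial protocol

- Wall luminance ramps logarithmically between 140 and 0.14 cd/m² at 1 or
  3 log₁₀ units/s (durations 3 s / 1 s), rendered at 90 Hz through the LUT.
- The stimulus is a Gaussian blob, FWHM 0.6° (σ = FWHM/2.355 ≈ 0.255°), at
  10° eccentricity in one of four corners (uniformly random per trial).
- The stimulus fades toward its target luminance at 0.3 log₁₀/s over
  333 ms, starting on the background side of the target so that Weber
  contrast `(L_stim − L_bg)/L_bg` grows monotonically in magnitude.
- Dim-end stimulus grey 14 (17 behind sunglasses), bright-end grey 230;
  4 s inter-stimulus interval; stimulus onset after ramp end.
- A session is 4 lenses × 2 rates = 8 conditions in shuffled order, each a
  block of 20 decrease then 20 increase trials (320 total).

Per-trial seeds are drawn from the session generator, so whole sessions are
reproducible from one seed.

## 4. Synthetic observer

The observer is a deliberately simple mechanistic stand-in for a human
participant — it exists to exercise the pipeline and validate the analysis
code, and its defaults are fixed study conditions, not quantities fitted to
this package's tests.

- **Baseline threshold:** θ(L) = θ_w·√(1 + L_half/L) (de Vries–Rose to
  Weber transition).
- **Adaptation state:** tracks the behind-lens log₁₀ luminance at a limited
  speed of 1/τ log-units per second (dark direction slower than light). The
  residual gap `g` at stimulus onset inflates the threshold by
  `penalty_gain · g^penalty_exponent`; the inflation decays exponentially
  with time constant `τ_dir · g`, lengthened by `scotopic_slowdown` per
  log₁₀ unit the onset luminance lies below `lum_scotopic`.
- **Detection:** first time the stimulus' Weber-contrast magnitude exceeds
  the effective threshold (closed-form contrast, root refined by Brent
  bracketing), plus Gaussian motor latency. Trials whose contrast never
  reaches threshold are recorded as misses.

Defaults: `contrast_threshold = 0.12`, `motor_latency = 0.80 s`,
`latency_sd = 0.15 s`, `adaptation_tau_dark = 0.5`,
`adaptation_tau_light = 0.25` (s per log₁₀ unit), `penalty_gain = 12`,
`penalty_exponent = 2`, `lum_half = 1 cd/m²`, `lum_scotopic = 0.1 cd/m²`,
`scotopic_slowdown = 1`. These were chosen once, by matching the qualitative
published pattern (decrease trials: fast self-tint fastest, sunglasses
slowest; increase trials: conditions indistinguishable), and then frozen.

## 5. Statistics

- Median and IQR via linear-interpolation percentiles.
- Paired condition comparisons: Wilcoxon signed-rank on per-participant
  medians. For N ≤ 16 the p-value comes from exhaustive sign-flip
  enumeration with average ranks, which stays exact under tied difference
  magnitudes; untied N ≤ 25 uses scipy's exact mode; larger N the normal
  approximation. Identical samples give p = 1. Optional Holm step-down
  correction within each direction panel.
- Learning effect: one-sided unpaired Student t comparing the first and
  last blocks of increase-direction trials.

## 6. Synthetic fixtures

`generate_calibration_fixture` emulates a photometer sweep: 3 repeats per
grey, mean power from the preset response, multiplicative Gaussian repeat
noise with relative SD 20 % (greys 0–7), 5 % (8–16) and 2 % (17–255).
These noise bands are fixed properties of the emulated instrument, not
tuning knobs.

## 7. Known limitations

- The synthetic observer separates the *slow* self-tinting lens from the
  static lenses only weakly in slow-ramp decrease conditions; its simple
  first-order adaptation dynamics cannot reproduce quantitative human
  medians and are not intended to.
- Published dim-end behind-lens grey/contrast cells are dominated by
  quantization (grey steps near the bottom of the range are ≈ 0.05–0.1
  log₁₀ units), so chain-recomputed dim Weber contrasts deviate from the
  printed two-decimal values; the bright-end cells reproduce exactly or
  within one grey step.
- One published dim-end sunglasses stimulus grey (37) is inconsistent with
  its own printed luminance column; the simulation uses grey 17, whose
  fitted luminance matches the printed behind-lens luminance and contrast.
- No GUI, live headset integration, pupil model, or photometer drivers.
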