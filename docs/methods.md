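# Methods

This note records the models, algorithms, parameter choices, and numerical
conventions implemented in `coralchron`, and what the synthetic test scenes
do and do not establish about real radiograph data.

## Densitometry model

Radiograph luminance is treated as linear in skeletal bulk density at fixed
slab thickness and exposure: `density = slope · L + intercept`. This is the
standard working assumption for coral X-ray densitometry at a single
exposure setting; no Beer–Lambert attenuation physics or beam-hardening
correction is modeled.

**Wedge calibration.** The calibration object is an aluminium wedge
(defaults: length 9.9 cm, taper 0.138°, material density 2.71 g cm⁻³). At
distance *s* from the thin end, the wedge thickness `t(s) = s·tan(0.138°)`
is converted to the density a slab of reference thickness (0.6 cm, the
milled slab thickness) would need to present the same areal mass:

    ρ_eq(s) = 2.71 · t(s) / 0.6     (ranging 0 → ≈0.108 g cm⁻³)

An ordinary least-squares line is fitted through the (luminance, ρ_eq)
pairs sampled along a wedge transect, plus a zero-density anchor at the
mean luminance of a user-specified air region. The anchor's weight defaults
to `n_samples / 10` — enough to pin the intercept without letting one
aggregate point dominate the wedge slope. Whether the historical
luminance–density calibration runs through aluminium-thickness equivalence
exactly this way is one consistent reading of the workflow; the linear-map
contract is unaffected by the parameterization.

Because the wedge spans only ≈0.11 g cm⁻³ of equivalent density while coral
is near 2 g cm⁻³, the fit extrapolates ~25× beyond the wedge range. The
slope must therefore be essentially unbiased: a systematic luminance
distortion of 0.1 % maps to ≈0.03 g cm⁻³ at coral densities. Two
consequences are built in:

- **Transect origin.** The equivalent-density formula measures *s* from the
  zero-thickness tip. If the drawn transect starts past the tip, pass
  `start_offset_cm`; otherwise the wedge line and the air anchor disagree
  and tilt the fit (this exact failure is reproduced in the test suite).
- **Flat-field correction.** Beam-intensity variation is multiplicative in
  exposure, so correction divides by the blank-plate image normalized to
  its own mean (Gaussian-smoothed, σ = 3 px, so plate shot noise is not
  imprinted). Mean luminance is preserved to ≪1 %; a uniform plate is the
  identity. A 10 % radial gradient that would corrupt the extrapolated
  density prediction by far more than 1 % is reduced to <1 % after
  correction.

Validation follows the two-standard convention: air (0 g cm⁻³) and a pure
aragonite slab of known density (2.93 g cm⁻³ for a *Tridacna maxima* shell
slab of coral-equivalent thickness), with a pass/fail report at a stated
tolerance (default ±0.05 g cm⁻³).

**Transect profiles.** Pixel coordinates are 0-based with the origin at the
top-left pixel center. Profiles are sampled at 0.25-px steps by bilinear
interpolation and averaged across an odd width perpendicular to the
transect; band widths near 0.2 cm at 50 µm pixels need this sub-pixel
resolution.

## Band delineation and annual metrics

The smoothed profile (moving average, default window 0.05 cm, forced to an
odd sample count so the filter is symmetric) is scanned for alternating
local maxima (HD centers) and minima (LD centers) with a prominence floor
of `max(0.02 g cm⁻³, 0.2 × (p95 − p5))` — the absolute floor makes a
constant profile return "no banding detected" rather than noise peaks. The
profile is padded below its minimum (for peaks) and above its maximum (for
troughs) so bands touching the profile ends are still found. The boundary
between two adjacent extrema is placed where the smoothed profile crosses
the midpoint of the two extremum values: for plateau-like bands this
half-amplitude crossing sits on the true transition regardless of the two
bands' relative widths, which a midpoint-of-centers rule does not achieve.
Bands narrower than `min_band_width` (default 0.05 cm) are merged into
their neighbors; ties in extremum competition resolve toward the earlier
(older) position for determinism.

Annual metrics per LD+HD couplet: extension = summed band lengths; density
= length-weighted mean of profile samples across the couplet (an unweighted
mean of the two band means is available as `density_mode="band_mean"`, since
"the average for each pair" admits both readings — length-weighted is the
default because that is what sampled profile data naturally give);
calcification = product, exactly, by construction. Couplets are labeled by
the calendar year of the HD (summer) band, counted backward from
`last_complete_year`; a record spanning years *a*–*b* carries *b − a*
increments labeled *a*+1 … *b*. The outermost couplet can be dropped
(`exclude_outermost`) when the youngest band may still be forming, as is
done with cores collected mid-deposition.

Overlapping transects are stitched on declared complete-couplet overlaps
(≥1 couplet, so no partial band crosses a join); within an overlap the
earlier, already-accepted segment's band lengths win, and a >5 % density
disagreement in shared couplets is recorded as a warning, not an error.
Manually measured band tables (CSV) are a first-class input alongside
automatic detection.

## Normalization and master chronologies

Cores are normalized additively: subtract the core's mean over its assigned
reference period, add back the group mean of those reference-period means.
Units are preserved and within-core anomalies are untouched (exactly — the
operation is a per-core constant shift). Default reference periods follow
the study design: "long" 1954–2020 and "short" 1993–2020, with automatic
assignment to the longest period a core fully covers and a manual override.
Cores too short for any period (the PB02/PB04 analogues) are excluded from
the group means but still normalized — using their own full-span mean,
since no other span is available for them — and included in the masters.
When a period's group mean is computed, only cores *assigned* to that
period contribute (long cores also cover 1993–2020 but do not enter the
short-period mean; this is the stricter of the two possible readings).

The master chronology is the per-year mean across cores with data that
year; SE = sample SD (n−1) / √n, undefined where fewer than two cores
overlap; per-year replication is reported. Decadal means use half-open
[y, y+10) windows anchored at the first year divisible by 10 in the span.

## STARS regime-shift detection

The sequential t-test analysis of regime shifts is implemented from its
definition so results are reproducible without any external package:

1. σ²_l = average sample variance over all consecutive windows of the
   cut-off length *l* (default 10 yr); critical difference
   `diff = t₍1−α/2, 2l−2₎ · √(2σ²_l / l)` (α default 0.05, two-tailed).
2. The initial regime mean is the mean of the first *l* values. Values
   within ±diff of the current regime mean join the regime (mean updated);
   a value beyond ±diff becomes a candidate shift.
3. The regime-shift index accumulates the exceedance beyond `mean ± diff`
   over up to *l* values starting at the candidate, normalized by `l·σ_l`.
   A negative running sum rejects the candidate immediately (it is absorbed
   into the regime); RSI = 0 also rejects. Survival over the full window
   confirms the shift at the candidate year.
4. Candidates whose confirmation window is truncated by the series end stay
   *tentative* (reported separately, never confirmed). Without this rule a
   single noise excursion in the final years confirms on one or two values
   and the family-wise false-alarm rate on 70-year white noise exceeds 50 %;
   with it the measured rate is ≈10 %, within the ~3× nominal bound expected
   for the method's effective level.

Growth series are log-transformed (natural log — the base only rescales
means, never shift years) before detection, matching the convention for
multiplicative growth variability. Boundary ties count as non-exceedance.
Huber outlier weighting and red-noise prewhitening from later STARS
variants are deliberately not implemented; only the cut-off length and
significance level are part of the specified procedure.

## Environmental statistics

Monthly series are aggregated per calendar year (mean by default; SSTmin
and SSTmax are the extrema of the twelve monthly means). Years missing more
than two months are dropped and reported. Annual precipitation uses the
mean of monthly values for consistency with "annual averages" of all
parameters; a sum option exists.

Station records are merged by OLS rescaling (`target = a + b·reference`)
over a declared overlap (≥24 paired months; gaps handled by inner join, not
imputation). Uncertainty comes from residual-bootstrap Monte Carlo:
residuals resampled with replacement, line refitted, mapping reapplied;
the per-month 95 % envelope is the 2.5/97.5 percentile band of replicate
predictions. This quantifies parameter (line) uncertainty — the envelope
covers the noise-free mapped value at ≈95 % per month, which is the
calibrated behavior the tests check — not the month-to-month scatter a
prediction interval would add.

Growth–environment association uses Pearson correlation (two-sided t,
n−2 df) and polynomial least squares (degrees 1–3; r², overall-F p) on
log-transformed growth, over the full span and over split sub-periods
(default 1950–1985 / 1986–2020, inclusive endpoints — the package reports
the resulting n transparently rather than silently dropping a boundary
year). Alignment is an inner join on calendar year with an optional lag
(default 0). p-values are reported unadjusted by default, matching the
headline workflow; `adjust_p=True` adds a Benjamini–Hochberg FDR column
across all tests in the output table.

## Synthetic scenes: what they emulate and what they do not

The generators are the test bed for every stage:

- **Growth series**: level + linear trend + step shifts + additive AR(1)
  anomaly (marginal SD specified; innovations scaled by √(1−φ²)).
  Positivity is enforced by flooring, not by a multiplicative noise model.
  Defaults (extension 0.45 cm yr⁻¹, density ≈2.0 g cm⁻³, AR(1) 0.3,
  anomaly SD 0.03 cm yr⁻¹) match the scale of published *S. siderea*
  records.
- **Radiographs**: density is piecewise-constant per band along the growth
  axis (LD fraction 0.45 of each year, LD/HD contrast 0.4 g cm⁻³ split so
  the length-weighted couplet mean equals the annual truth exactly).
  Rendering is anti-aliased along the growth axis — each pixel carries the
  mean density over its ±0.5 px extent — so true boundaries live at exact
  fractional pixel positions; the optional rotated mode uses
  nearest-band sampling. Luminance = inverse calibration × radial
  vignetting gain (1 − amp·ρ²) + Gaussian noise, clipped and quantized to
  the bit depth. 16-bit scenes map air to 62 000 counts and 0–3.2 g cm⁻³
  across the full range.
- **Environment**: sinusoidal seasonality + linear trend + noise, clipped
  at zero for precipitation/discharge; logistic population curve.

Not emulated: skeletal micro-architecture (corallite in-filling), density
variation within a band, bioerosion voids, film-grain artifacts, wedge
misalignment, or operator digitization error. Passing the recovery tests
therefore demonstrates the algorithms are correct and sub-pixel accurate on
idealized banded structure with realistic noise levels — not that band
detection is operator-grade on difficult real slabs, which is why manual
band tables remain a first-class input.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen to exercise the
statistics honestly: 20–30-year cores at 50 µm pixels, 20 seeds for
boundary-recovery sweeps, 500/200 simulations for the STARS false-alarm and
power checks, 50 seeds × 300 bootstrap replicates for rescaling coverage,
and a 12-core demo matching the published core spans. Every stochastic
component takes an explicit seed (`numpy.random.default_rng`); the pipeline
splits one root seed deterministically per core and stage, and a rerun from
the same config is byte-identical across its CSV/JSON outputs.

## Known limitations

- The calibration extrapolates far beyond the wedge's equivalent-density
  range by design; any nonlinearity of the real detector response is
  absorbed silently. The aragonite standard is the only in-range check at
  coral densities.
- Band detection assumes one dominant band frequency; double banding or
  stress bands will be merged or split by the `min_band_width` rule.
- STARS is run without autocorrelation correction; on strongly red series
  its effective false-alarm rate exceeds the nominal level.
- The rescaling envelope ignores reference-station measurement error in the
  predictor (errors-in-variables attenuation of *b* is not corrected).
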