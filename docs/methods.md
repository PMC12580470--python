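# Methods

This note documents the statistical procedures the package implements, the
choices made where a convention had to be fixed, and what the synthetic
study generator does and does not emulate.

## Event definition and trapping effort

Raw camera triggers are collapsed into independent events per camera ×
class. A trigger starts a new event when its gap to the **immediately
preceding trigger** of the same key is at least the class threshold;
anything closer extends the current event (record-to-record chaining, so an
arbitrarily long burst of closely spaced triggers is one event). The
comparison is `gap >= threshold -> new event`. Thresholds: 8 s for
recreational activity, 300 s for wildlife. Group size is deliberately
ignored — a group of ten animals counts the same as one; the indices below
measure how often a species is recorded, not how many individuals pass.
The filter is idempotent and keys on camera × class; whether wildlife
filtering should key on camera only is unresolved in the field, and per
camera × species is the convention adopted here.

Trapping days are whole calendar days a camera was active and unobstructed:
the intersection of the deployment window with the stratum window, minus
the **union** of exclusion intervals (overlapping intervals are not double
counted). Partial first/last days count as active. Exclusions extending
outside the deployment window are clipped with a warning.

## Hunting effort strata

Each study month is classed by its share of successful hunting events
within its own calendar year: low < 5%, medium 5–10% (both boundaries
inclusive to medium), high > 10%. Using the year rather than the study
window as the denominator keeps a month-of-year's label stable when a study
spans the same months twice; with a 14-month window a window-total
denominator would push genuinely medium months below the 5% line.
Non-contiguous windows with the same label — the two high-effort hunting
seasons — form one pooled stratum, but stay separate as *periods* wherever
a per-season quantity is needed (the recreation median split).

## Relative abundance and trail index

RAI = 100 · (independent events) / (trapping days), pooled over a stratum's
cameras; algebraically this is the trap-day-weighted mean of per-camera
RAIs. The trail index is ln((RAI_trail + 1)/(RAI_forest + 1)) — the natural
log, which reproduces the published worked values where log₁₀ does not; the
+1 shift keeps zero-event strata finite. The index is antisymmetric under
swapping trail and forest and increasing in trail use.

Uncertainty is a nonparametric bootstrap over camera **locations**: ids are
resampled with replacement (B = 1000) and a resampled location contributes
both its trail and its forest camera, so the trail and forest RAIs inside a
replicate come from the same draw. Intervals are percentile (2.5%/97.5%);
no bias correction is applied. Replicates on which a statistic is undefined
(all resampled trap days zero) are dropped and counted, not imputed.
Contrasts — forest vs trail within an effort, trail index across efforts —
use the *same* location draws in both arms and difference
replicate-by-replicate; this paired differencing is conservative and reuses
the stated location-level resampling. A contrast is flagged significant
when its 95% CI excludes zero.

On synthetic data with Poisson event counts and a known rate, the 95%
percentile CI on a 20-location pooled RAI covers the truth in 90–99% of 200
independent datasets (the test suite recomputes this).

## Solar geometry

Solar position uses the standard NOAA low-precision ephemeris (fractional
year → equation of time and declination → hour angle → altitude), accurate
to well under 0.5° — about a minute of event timing at the study latitude.
Crossing instants are refined by root finding (Brent) on the altitude
function to sub-second precision. Rise/set uses the conventional −0.833°
altitude (refraction plus solar radius); nautical twilight uses exactly
−12°. High latitudes where a crossing does not exist raise an explicit
error rather than a silent fallback.

Night is the half-open interval from evening nautical-dusk onset to morning
nautical-dawn end: an event exactly at dawn end is day, one exactly at dusk
start is night.

Clock time maps to solar radians by the double-anchored ("equinoctial")
transform with **date-specific** sun times: [sunrise, sunset] stretches
linearly onto [π/2, 3π/2] and each night onto [3π/2, 2π + π/2] (mod 2π).
The transform is continuous, monotone, and bijective over any 24 h window.
Average-anchored variants exist; date-specific anchoring is what is
implemented and tested here, and the two are not interchangeable at
solstices.

By default one reference location (49.0° N, 13.4° E, roughly the centroid
of a 250 km² mid-latitude park) serves all cameras; per-camera coordinates
are accepted, but across < 0.5° of extent the twilight times differ by
under two minutes.

## Disturbance subsets and activity curves

Per species, events are partitioned by effort (3) × placement (2) ×
recreation intensity (2) × hunting-zone membership (2) = 24 subsets.
Recreation intensity is a median split of the per-camera recreation RAI
within each effort period (the two high seasons split against their own
medians, then pool): RAI < median → low, ≥ median → high, so with an even
number of distinct values the split is exactly half/half, and with all-equal
values everything is deterministically "high". Forest cameras inherit their
paired trail camera's label; cameras without a pair are excluded and
logged. Subsets with fewer than 10 independent events are dropped from
curve estimation and reported.

The activity density is a von Mises kernel estimate,
f(θ) = (1/n) Σᵢ exp(κ·cos(θ − tᵢ)) / (2π I₀(κ)), on a 512-point half-open
grid. The concentration κ is a plug-in: the kernel's circular SD is matched
(by root finding on the Bessel ratio I₁/I₀) to 1.06 · σ̂ · n^(−1/5), the
normal-reference rule transplanted to the circle with σ̂ the sample
circular SD, times a user `bandwidth_adjust`. Envelopes are pointwise
2.5/97.5 percentiles over B = 1000 resamples of the event times (a data
bootstrap, computed as multinomial reweightings of the kernel matrix, so
the envelope cost is one matrix product). The density integrates to 1 to
10⁻⁶ by construction and is equivariant under circular shifts. The overlap
coefficient ∫ min(f, g) is provided for comparing two curves on a common
grid; no formal curve-difference test is attempted.

## Nocturnality model

Per camera × effort stratum, the night event count out of the total is
modelled as beta-binomial in the mean–precision parameterization:
n_night ~ BB(n_total, α = μφ, β = (1−μ)φ) with logit(μ) = Xβ and precision
φ > 0 absorbing overdispersion (φ → ∞ recovers the binomial). The
log-likelihood is computed directly with log-gamma arithmetic and is stable
for counts to at least 10⁵ per row.

The design crosses effort (treatment-coded, reference **high**) and
placement (reference **trail**) with each continuous covariate — distance
to the hunting-zone border (m), recreation RAI at the paired trail camera
(the two high seasons pooled, events-weighted), and a visibility layer —
including all two- and three-way interactions. With the reference at the
most-disturbed cell, coefficients read as departures from it. Continuous
covariates are z-scored with stored constants so predictions can be mapped
back to natural units; optional per-species transforms (log1p replaces,
quadratic adds a squared copy) are applied before scaling, because the
appropriate curvature terms are species-specific and must be configurable
rather than hard-coded. The default species → visibility-layer mapping
follows eye height: 140 cm for red deer, 70 cm for roe deer and wild boar,
50 cm for red fox and lynx; the intermediate assignments are package
defaults, configurable per run. Constant covariates are dropped with a
warning and rank deficiency is reported.

Estimation maximizes the likelihood over (β, log φ) with L-BFGS-B
(`method="ml"`), optionally with a ridge penalty equivalent to N(0, 2.5²)
priors on the scaled coefficients (`"map"`); the Bayesian machinery of the
original modelling tradition is infrastructure rather than a scientific
claim, and ML on the same likelihood tests the same model. Standard errors
come from the inverse observed information (central-difference Hessian at
the optimum); φ's SE is delta-method from log φ. Non-convergence is flagged
and partial results returned with a warning. A random-walk Metropolis
sampler over the matching posterior (half-normal prior on φ, sd 50) is
available as a cross-check, not the primary estimator. Predictions are
inverse-logit of Xβ with normal-approximation intervals on the linear
predictor; the predicted index crosses 0.5 exactly where Xβ crosses 0.

Under the generator below, 100 simulated studies of 200 camera-strata with
~50 events each recover ≥ 95% of coefficients within 3 SEs (recomputed by
the test suite). With little true overdispersion the φ estimate is weakly
identified upward (any large φ fits), which is expected and harmless for
the mean-model coefficients.

## Synthetic study generator

Defaults emulate the study design the pipeline targets: 61 paired
trail/forest locations (122 cameras), a study window from 15 Nov 2020 to
5 Dec 2021, coordinates in a 48.9–49.1° N × 13.2–13.6° E band, 40% of
locations inside the hunting zone (distance 0) and the rest at distances
drawn up to 3933 m, visibility covariates drawn within the observed ranges
at 50/70/140 cm, and month-of-year hunting weights
(14, 3, 3, 3, 3, 6, 6, 7, 7, 15, 18, 15) chosen so Feb–May fall below 5%,
Jun–Sep in 5–10%, and Oct–Jan above 10% of the yearly total — producing two
high seasons that pool into one stratum. Monthly hunt counts are
deterministic (weight-proportional) so the strata are a fixed property of
the configuration, not a random draw.

Event counts per camera-day are Poisson — the minimal counting model, under
which the pooled RAI is an unbiased rate estimate. Clock times are drawn in
two stages: first night vs day by the inverse-logit of the configured
coefficient vector applied to that camera × effort's covariates (z-scored
across the generated study exactly as the fitted model will z-score them),
then a time from the species' von Mises mixture restricted to the chosen
period by rejection against the twilight classifier (falling back to a
uniform draw within the period if the mixture carries essentially no mass
there). This makes the beta-binomial regression correctly specified under
the generator, which is what clean parameter recovery requires. Camera
outages are independent Bernoulli days (p = 0.02) compressed into exclusion
intervals; no event is ever placed on an excluded day. Recreation events
occur on trail cameras only, with lognormal per-camera daily rates (mean 6,
σ = 0.8 on the log scale), a midday-peaked clock-time distribution, and a
15% chance that an event is a burst of extra triggers 1–6 s apart — placed
there deliberately so the 8 s rule is exercised rather than vacuous.

What the generator does **not** emulate: spatial autocorrelation between
cameras, animal movement (events are independent given the daily rate,
with no within-day clustering for wildlife), seasonal changes in the
circadian mixture itself, detection-probability differences between
cameras, and real overdispersion sources beyond the beta-binomial's own.
Passing tests therefore demonstrate that the estimators recover the truth
of this data-generating process at the study's size and rates — not that
the field data satisfy these assumptions.

## Problem sizes and determinism

The analysis drivers run the full 61-pair study with B = 1000 bootstrap
and envelope resamples (a few seconds per stage). The test suite exercises
the same code paths on an 8-pair study with B = 100, plus the dedicated
coverage (200 datasets × B = 1000) and recovery (100 fits) simulations;
these sizes were chosen as the smallest at which the checked frequentist
properties are meaningful. All randomness flows from explicit seeds through
`numpy.random.Generator`; rerunning any stage with the same seed reproduces
its outputs byte-for-byte, and that reproducibility is itself under test.

## Known limitations

* The RAI is a use-intensity index, not density; no detection-probability
  correction is attempted.
* Percentile bootstrap intervals can undercover at small location counts
  or very low rates (rare-event strata); the lynx-like strata in the
  synthetic study sit near that edge.
* The plug-in KDE bandwidth targets unimodal smoothness; strongly bimodal
  crepuscular patterns are slightly oversmoothed at small n.
* `is_night` and the solar transform trust the one-reference-location
  default; studies spanning > ~1° should pass per-camera coordinates.
* The beta-binomial fit reports a convergence flag and gradient norm but
  does not attempt restarts; pathological designs (quasi-separation in a
  small stratum) surface as large SEs rather than refusals.
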