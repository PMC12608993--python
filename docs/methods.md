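# Methods

This note documents the statistical machinery in `camoverlap`, the
conventions it fixes where the field leaves room, and what its tests do and
do not demonstrate.

## Detections, effort and abundance

A *trigger* is one camera event (photo burst or video).  Triggers of the same
species at the same station are thinned to **independent detections** with a
quiet-period rule: a trigger is kept if it falls at least `window_minutes`
(default 30) after the **previously kept** trigger of that (station,
species) group; the first trigger of a group is always kept, and a gap of
exactly the window counts as independent.  The rule is idempotent,
order-deterministic, and never lets different species or stations suppress
each other.  Two alternatives exist in the literature (fixed clock bins;
gap from the previous raw trigger); the retained-event rule is the common
convention and the one implemented.

**Trap-days** count whole days in `[start, effective_end)` — an
exclusive-end convention in which the retrieval/planned-end day does not
count.  When a camera failed, its last photo day marks the final operational
date and *is* counted (`effective_end = last_photo + 1 day`, capped at the
planned end).  A deployment whose start and end coincide contributes one
trap-day.  These conventions matter only at the margins but must be fixed
for reproducibility.

**RAI** (relative abundance index) is `100 × independent detections /
trap-days`, per station and species or survey-wide.  The **human-presence
covariate** is the RAI of human/domestic-animal triggers at a station; it is
passed through the same independence filter by default (the choice is
exposed because survey protocols differ on this point).

## Solar time

Comparing times of day across a year-long survey requires removing seasonal
day-length change.  The default transform double-anchors each day: sunrise
maps to π/2 and sunset to 3π/2, with linear interpolation inside the
daylight and night segments, so the map is piecewise linear with exactly two
pieces and strictly increasing through the day.  An event "two hours after
sunset" lands on the same angle in June and December.

Sunrise and sunset come from the standard NOAA solar-position equations:
Fourier series for the solar declination and the equation of time in the
fractional year, and the hour angle at the conventional −0.833° solar
altitude (refraction plus semi-diameter).  Accuracy is within a few minutes,
well below the kernel bandwidths used downstream; the transform refuses
latitudes beyond ±66.5° where days without sunrise/sunset occur.  Two other
modes are exposed: `equation_of_time` (apparent solar time, equalises solar
noon but not day length) and `none` (raw clock time).  Per-station
coordinates are used when available; a single survey-wide location is a
configuration away.

The generator inverts the same map, so synthetic activity defined in solar
angles round-trips exactly through the analysis path.

## Circular kernel density estimation

Activity densities are mean von Mises kernels,
`f̂(x) = (1/n) Σᵢ vM(x; μ=tᵢ, κ)`, evaluated on an equally spaced grid on
[0, 2π) (128 points by default) and renormalised so the periodic trapezoidal
integral is exactly 1.

**Bandwidth.** The kernel concentration κ follows the circular rule-of-thumb
plug-in: estimate the sample concentration κ̂, then

    κ = [ 3 n κ̂² I₂(2κ̂) / (4 √π I₀(κ̂)²) ]^{2/5} / adjust.

Diel activity is typically bimodal, and for near-antipodal peaks the plain
von Mises ML estimate of κ̂ collapses towards zero (the two modes cancel the
first resultant), which would oversmooth the estimate into near-uniformity
and inflate overlap coefficients by +0.1 or more.  κ̂ is therefore taken as
the largest of the estimates from the first three trigonometric moments,
each scaled back to the data scale by k² (a concentrated component of
concentration κ has concentration ≈ κ/k² on the k-fold wrapped circle).
`adjust` defaults to 0.8 for Δ̂₁ and 1.0 for Δ̂₄, the values established in
the overlap-estimation literature; leave-one-out likelihood cross-validation
is available as `bandwidth="cv"`.  Degenerate samples (all points identical)
cap κ at 500 with a warning.

Large evaluations (> 4×10⁶ point-kernel pairs) compute the density on a
1024-point grid and interpolate linearly with periodic wrap-around; the
interpolation error is orders of magnitude below the estimators' sampling
noise while the cost becomes linear.

## Overlap coefficients

* **Δ̂₁** integrates `min(f̂, ĝ)` over the common grid (periodic trapezoid).
* **Δ̂₄** is `½[ meanᵢ min(1, ĝ(xᵢ)/f̂(xᵢ)) + meanⱼ min(1, f̂(yⱼ)/ĝ(yⱼ)) ]`,
  the cross-evaluated ratio estimator, with densities floored at machine-ε.

The estimator is selected per pair by the sample-size rule used in the
camera-trap literature: Δ̂₄ when the **smaller** sample has ≥ 75 independent
detections, Δ̂₁ otherwise (the threshold is configurable; the rule is applied
to the minimum because the pair's weaker estimate limits both).

Both estimators are clamped to [0, 1], symmetric, and invariant to a common
rotation of both samples.  At n = 500/side Δ̂₄ carries a small smoothing bias
(about +0.01 to +0.02 at intermediate overlap, slightly negative near 1) with
a sampling SD of ≈ 0.025; in repeated truth-known experiments about 92–95% of
replicates fall within ±0.05 of the quadrature-oracle value.

**Confidence intervals** use a smoothed bootstrap: resample each sample's
times from its fitted KDE (pick a datum, add von Mises kernel noise),
re-estimate Δ with the same estimator, and take percentile 2.5/97.5 bounds
(1000 replicates by default, fully seeded).  The interval is widened if
necessary to bracket the point estimate — smoothed replicates are biased low
for near-identical samples — and clamped to [0, 1].  The basic (reflected)
interval is a known alternative; percentile is the default here and the
difference is well inside the interval widths at survey sample sizes.

## Watson–Wheeler test

Whether two angular samples share a distribution is tested with the
uniform-scores (Watson–Wheeler) statistic: pool the N = n₁+n₂ angles, rank
them around the circle, set γ = 2π·rank/N, and

    W = 2 Σₖ (Cₖ² + Sₖ²) / nₖ,   Cₖ = Σ cos γ, Sₖ = Σ sin γ within sample k.

Under the null W is asymptotically χ² with 2 df.  Minute-resolution camera
data produce ties: tied angles receive averaged ranks with a warning, and
when more than 10% of the pooled sample is tied the χ² reference is refused
and a seeded label-permutation p-value (`method="permutation"`) must be used
instead.  Samples below 10 per side trigger an accuracy warning.  Calibration
checks (2000 null replicates at n = 100/side) put the empirical type-I error
at nominal α = 0.05 within [0.03, 0.07].

## Spatial and spatiotemporal overlap

Pianka's index is computed on per-station RAI vectors over a common station
set; it is scale-invariant, so raw RAI and normalised proportions give the
same value.  Stations with zero trap-days are excluded (logged).  The 95% CI
resamples **stations** with replacement, the pair's entries travelling
together; degenerate resamples (either vector all zero) are redrawn with a
logged count.  The resampling unit is the station because the RAI vector is
station-indexed — detections within a station are not exchangeable across
stations.

A caveat that matters for sparse species: RAI entries are Poisson-noisy, and
noise inflates the denominator `√(Σp²Σq²)`, attenuating the index below its
intensity-level value by roughly `[(1 + 1/(λ̄(1+cv²)))(…)]^{-1/2}` for mean
per-station counts λ̄.  With a few detections per station this bias reaches
−0.1 to −0.2.  Truth-recovery tests therefore use designs with ≈ 80 expected
detections per station, where the attenuation is negligible; with real
sparse data, Pianka values for rare species should be read as conservative.

**Spatiotemporal overlap** is the product Δ × O per predator–prey pair and
stratum, in [0, 1] and bounded by min(Δ, O).  No CI is propagated for the
product by default (a delta-method interval is a straightforward extension),
matching how such products are reported.

## Stratification

Stations are split into three classes per covariate.  Breaks are either
explicit or the first/third quartiles of the observed distribution
(linear-interpolation quantiles).  The middle class is the **closed**
interval [lower, upper]; values strictly below/above go to the outer classes
— the convention that matches printed "<a / a–b / >b" class definitions.
Shipped defaults: human presence 1.98/4.39 detections per 100 trap-days,
distance to settlement 500/1000 m, distance to road 400/1000 m, altitude
500/800 m.  Seasons: warm = May–October by detection date, cold otherwise.
Gradient strata are station properties (a detection inherits its station's
class); seasons are detection properties, and seasonal RAI uses seasonal
trap-days counted day by day.

The pipeline emits one row per scheme × stratum × pair, including rows with
missing statistics (and a reason) when a cell has fewer than two detections
of either species, so the output grid is always complete, and an
unstratified "overall" pass whose detections equal the union of any
gradient's strata.

## Synthetic surveys and oracles

The generator emulates the structure the analysis assumes, at the scale of a
subtropical-reserve survey: 180 stations and a ~11-month deployment
(~60,000 trap-days) by default, with a 5% camera-failure rate truncating
deployments at a last-photo date.  Station covariates are drawn to produce
realistic gradients (altitude ≈ N(660, 230) m clipped to the reserve's
273–1538 m range; log-normal distances to road and settlement with quartiles
near the default class breaks; log-normal human activity rates averaging a
few detections per 100 trap-days).  Species are defined by

* a von Mises mixture in solar radians for diel activity — the four presets
  are a crepuscular-nocturnal predator (peaks ≈ 04:00 and 20:00 solar,
  survey-wide rate 0.5 per 100 trap-days), abundant nocturnal rodents
  (≈ 17/100), and two diurnal prey with dawn/dusk peaks (≈ 1.0 and
  0.85/100), mirroring the detection-rate magnitudes and day/night structure
  of the community the pipeline targets; their generating overlaps with the
  predator are ≈ 0.68 (rodents), 0.24 and 0.18 (diurnal prey);
* a log-linear rate `λ = base_rate · exp(Σ β_c z_c)` on standardised
  covariates, with signs chosen so prey tolerate settlements more than the
  predator does (a human-shield-like configuration).

Counts are Poisson(λ × trap-days); event days are uniform over the
deployment; solar angles are drawn from the mixture and pushed through the
inverse solar map to clock timestamps.  A `clustered` mode adds geometric
bursts of extra triggers inside the independence window to exercise the
filter.  Everything is reproducible from a single seed.

What the generator does **not** emulate: spatial autocorrelation of
covariates or detections, within-day rate–covariate interactions (activity
shape is covariate-independent per species), imperfect detection, seasonal
activity shifts, or species misidentification.  Passing truth-recovery tests
therefore show the estimators are correct under the model's assumptions, not
that those assumptions hold in any particular field dataset.

Two oracles provide truth: `true_delta` (adaptive quadrature of
`min(f, g)` over the generating mixtures, tolerance 1e-8) and `true_pianka`
(Pianka's formula on expected per-station intensities).  They share no code
with the estimation path.

## Problem sizes in tests

The default test suite and the acceptance script are sized for a single CPU:
Δ̂₄ recovery uses 100 replicates of n = 500/side per target; Pianka recovery
uses 100 replicates of a 25-station, ~2000-detections-per-species survey;
null calibration uses 2000 replicates at n = 100/side; the end-to-end
determinism check runs a 60-station, 5-month survey twice with 100 bootstrap
replicates.  Full-scale surveys (180 stations, 10⁴ detections of an abundant
species, 1000 bootstrap replicates) run in minutes rather than seconds; the
grid-interpolated KDE evaluation keeps the cost linear in sample size.

## Known limitations

* Bootstrap CIs are percentile intervals; no studentisation or BCa.
* The Δ product with Pianka has no propagated uncertainty by default.
* RAI-based Pianka is attenuated for sparse species (see above).
* The solar transform assumes station clocks share one UTC offset and
  ignores daylight-saving changes.
* The Watson–Wheeler χ² reference is approximate below ~10 detections per
  side; the permutation method is the fallback.
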