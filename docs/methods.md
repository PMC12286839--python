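# Methods

`mothcompass` implements the statistical pipeline of a stellar-compass
orientation study on a nocturnal migratory moth: circular statistics on
tethered-flight heading trajectories, directional-tuning analysis of spike
trains recorded under rotating night-sky stimuli, and the algorithms that
build intensity-matched randomized control stimuli.  A synthetic-data
module emulates each stage's data-generating process so that the entire
pipeline is testable end to end without any recorded data.

## Angle conventions

All angles are compass degrees: 0° = geographical north, increasing
clockwise, reduced modulo 360.  Internally a compass angle `a` is
represented by the unit vector `(cos a, sin a)` in the compass frame (first
component north, second east), so `atan2(east, north)` returns compass
degrees directly; this is the single compass↔math conversion used
everywhere.  Two turn measures are provided: the signed shortest arc
(`circ_diff`, in (−180, 180]) and the directed turn in a fixed rotational
sense (`directed_turn`), which is the appropriate measure when an animal
reorients by more than 180° in a known direction — e.g. a cohort turning
clockwise from a mean heading of 168° to 355° has turned 187°, not the
173° shortest arc.

## Circular statistics

**Mean vectors.**  A trajectory of headings θ₁…θₙ is reduced to its first
trigonometric moment: mean direction α and resultant length (directedness)
r ∈ [0, 1].  A population of animals is summarized by the r-weighted
population vector — each animal contributes a vector of length r in its
mean direction — so poorly oriented animals pull the population vector
toward zero.  Degenerate r = 0 vectors carry an explicit undefined-direction
flag rather than propagating NaN silently.

**Moore's modified Rayleigh test.**  For n second-stage vectors (αᵢ, rᵢ),
the vectors are ranked by length (average ranks on ties) and the statistic
is R* = |Σᵢ rank(rᵢ)·(cos αᵢ, sin αᵢ)| / n^{3/2}.  Unlike the classic
Rayleigh test it uses both the direction *and* the directedness of each
animal.  No closed-form null is available, so p-values come from a seeded
Monte-Carlo permutation null (default 10 000 replicates): under the null
the direction of each vector is uniform and independent of its length, so
R* is distributed as the rank-weighted resultant of n uniform unit vectors.
The MC null is cross-checked in the tests against the asymptotic tail
P(R* > c) = exp(−3c²) that follows from the CLT for the rank-weighted
resultant (Σ i²/(2n³) → 1/6 per component).

**Rayleigh test.**  Classic Z = n·r̄² with the standard series
approximation for the p-value; used for first-order samples such as the
per-cell preferred angles.

**Mardia–Watson–Wheeler test.**  Two-sample uniform-scores test: pooled
ranks (average ranks across ties) are mapped to uniform scores
β = 2π·rank/N and W = 2·Σⱼ (Cⱼ² + Sⱼ²)/nⱼ is referred to χ² with 2 d.f.
Samples below 10 observations trigger a warning.

**Likelihood-ratio test for a common mean direction.**  Each sample is
modelled as von Mises.  Under H₁ each sample has its own (μⱼ, κⱼ); under
H₀ the mean direction is shared, with per-sample concentrations profiled
out analytically via κ̂ = A⁻¹(r̄ cos(μ̄ − μ)), A = I₁/I₀; the profile
likelihood over μ is maximized by a grid-plus-bounded search on the arc
between the two sample means.  2·(logL₁ − logL₀) is referred to χ² with
1 d.f.  A⁻¹ uses Fisher's piecewise approximation refined by Newton steps.
Near-uniform samples (r̄ < 0.05) warn that κ̂ is unstable.

**Confidence intervals.**  The study's source material does not state how
its population CIs were computed; we use a percentile bootstrap (default
10 000 resamples, seeded): animals are resampled with replacement, the
weighted population direction recomputed, and the half-width of the central
95% interval of bootstrap directions about the point estimate is reported.
Empirical coverage at study-scale populations (n = 50 animals) is ~94.8%
(computed in the test suite); smaller populations undercover slightly, as
percentile bootstraps do.

**Circular s.d.**  √(−2 ln r̄), converted to degrees; r̄ = 0 is reported
as infinite dispersion.

## Behavioural pipeline

Heading logs are tab-separated text (versioned header; columns `time_s`,
`heading_deg`) with a YAML metadata sidecar carrying moth id, season,
condition, arena, date, the stop-event count and the two pre-experiment QC
flags.  Stop events are explicit annotations — flight interruptions are a
procedural observation that cannot be reconstructed from the heading stream.
The reader wraps headings to [0, 360) and verifies (but does not alter) the
3° encoder quantization, erroring on malformed rows with their line number
and warning on sampling gaps > 1 s.

Inclusion requires: vertical tethering stalk, vigorous symmetric wing beat
(both metadata flags), at most 3 flight stops (the fourth stop rejects the
trial), and a full-length recording (300 s ± 5 s tolerance; partial logs
are excluded with reason `partial_log`).  Rejection percentages are
reported to one decimal (half-up rounding).

Each included trial is reduced to its mean vector over every 5 Hz sample,
unweighted and without detrending — the simplest faithful reduction of the
virtual flight path.  Population analysis then computes the weighted
population vector, Moore's test and the bootstrap CI; between-condition
comparisons use the MWW test on per-moth mean directions and the von Mises
LR test on condition means.  Paired early/late sessions are compared by the
per-moth signed heading change (late − early, shortest arc), its circular
mean, and a bootstrap CI; directedness cohorts split moths into
both-r > 0.8 / one-r > 0.8 / intermediate / both-r ≤ 0.2 groups.

## Neural tuning pipeline

Sweeps rotate the sky 360° at 30–45°/s, CW and CCW; spike times are mapped
to rotation angle (CW adds, CCW subtracts, plus the initial-heading
correction of 0/90/180° for the moth's mounting orientation), binned at 1°
(dwell per bin = 1/velocity) and smoothed with a circular Gaussian
(default σ = 5°, configurable — the filter bandwidth is a free choice).
Binning and smoothing conserve total spike mass to 1e−9.

**Model family and classification.**  Spike-angle distributions are fit by
maximum likelihood to M1 (uniform), M2A (von Mises), M2B (half von Mises +
half uniform), M2C (free-weight von Mises + uniform), M4A (equal-weight
axial pair vM(μ) + vM(μ+180°), shared κ) and M4B (free-weight axial pair),
selected by AIC.  Likelihoods are evaluated on 1°-binned spike counts; for
inhibited cells — whose spike distributions are *dips* that no positive
von Mises mixture can represent — the likelihood is evaluated on the
per-bin firing deficit (baseline − observed, clipped at 0), i.e. on the
mass of missing spikes.  The response sign itself (excited vs inhibited)
is judged by whether the pooled smoothed curve deviates further above or
below the pre-stimulus baseline.

Three guards keep the selection honest on noisy data:

* a response screen before model selection — a cell whose pooled spike mass
  shows no structure in either the first or the doubled (axial) circular
  moment (weighted Rayleigh p > 0.05 on both) is classified uniform,
  protecting AIC from anointing spurious low-amplitude tuning on large
  spike counts;
* a bimodal call requires the M4 family to beat the best unimodal model by
  ΔAIC ≥ 2 *and* a balanced mixture (both components ≥ 0.3 of the mass):
  M4B with λ → 1 is a unimodal shape in disguise, and a mixture more
  lopsided than ~70/30 has no second visible peak;
* per-direction model disagreement counts toward direction selectivity only
  at the family level (uniform / unimodal / bimodal) and only when both
  directions select their family decisively (ΔAIC ≥ 2).

Direction selectivity is DS = |p_CW − p_CCW| / (p_CW + p_CCW) ≥ 0.3
(threshold configurable) measured at the fitted preferred angle(s) (±15°
window — the global curve maximum is upward-biased for the weaker
direction), or decisive family disagreement as above.  Categories:
unimodal and not DS → 1 (excited) or 2 (inhibited); unimodal and DS → 3;
bimodal → 4.  Cells with fewer than 30 spikes are unclassifiable.

**φ_max.**  Per sweep, the rate-weighted circular mean of the smoothed
curve above baseline (excited) or of the inverted deficit (inhibited, so an
inhibited cell's φ_max marks its trough, not the antipode).  The cell-level
φ_max defaults to the μ of the pooled model fit, which weights each
direction by its response mass (the circular mean of the per-direction
estimates, or a single direction, are available as options).  Across-sweep
variability is the circular s.d. of per-sweep φ_max.

**Half-width.**  Excited cells: bootstrap over spikes (default 1 000
resamples, seeded; resampling is implemented as multinomial resampling of
the binned counts, which is equivalent and fast) of the interquartile range
of the fitted von Mises component.  Inhibited cells: width of the smoothed
inverted curve at half its modulation depth, i.e. at the level midway
between the curve extremes; for a noiseless von Mises profile this equals
the closed form cos θ_½ = 1 + ln((1 + e^{−2κ})/2)/κ, full width 2·θ_½.
Bimodal cells: not applicable.

**SNR.**  Per sweep: maximum smoothed in-rotation rate divided by the
s.e.m. of the pre-stimulus rate in 1-s bins (default 5 s window,
configurable — the window length is a free choice).  Zero pre-stimulus
variance flags the sweep's SNR as infinite and excludes it from summaries.

## Stimulus algorithms

Stimuli are 8-bit greyscale rasters; the reference natural stimulus spans
grey levels 4–255 with mean ≈ 62.  Star detection computes the
scale-normalized negative Laplacian of Gaussian at σ ∈ {1, 1.5, 2, 3, 4.5,
6.5} px (configurable; the source material does not state the scale range),
finds local maxima of the 3-D scale-space response above a threshold
(default 0.04 on a 0–1 intensity scale) and merges overlapping detections,
keeping the stronger.  A star's footprint is the set of pixels within 3σ of
its centre at ≥ 10% of its peak intensity; the brightest star is the one
with the highest peak (ties broken by integrated flux).

Three randomizations, all intensity-preserving:

* **pixel shuffle** — an exact permutation of all pixels (histogram
  preserved bit-for-bit);
* **13×13 block shuffle** — tiles permuted with interiors untouched (13 px
  matches the extent of the brightest star, so stars survive but the
  large-scale pattern does not); edge margins not divisible by 13 stay in
  place;
* **star-level shuffle** — detected star footprints are re-placed without
  overlap (rejection sampling, 10 000 retries before erroring), uniformly
  at random except the brightest star, which is pinned to the image
  centre, on a uniform background equal to the rounded mean of all
  non-star pixels (global mean preserved within ±1 grey level).

Coordinates are 0-based (row, col), row-major, documented in the catalog
file header.

## Synthetic data: what it emulates, and what it does not

**Headings** (`gen_heading_population`): each moth's mean heading is von
Mises about the population mean (κ_between, default 6 — between-moth s.d.
≈ 23°, emulating a well-oriented migratory cohort such as the moths above
the r > 0.8 directedness threshold; chosen by power analysis so that a
population of 40 moths determines its mean direction to a few degrees);
5 Hz samples are von Mises about the moth mean (κ_within, default 2.9,
giving per-trajectory r ≈ A(2.9) ≈ 0.8) with optional linear drift
(deg/min, default 0, emulating the slow within-trial wander of weakly
oriented moths) and 3° quantization; stop events are Binomial(minutes,
stop_prob).  Not emulated: serial correlation of real flight paths
(samples are i.i.d. given the mean), turning dynamics, optic-flow coupling.
Passing recovery tests therefore shows the estimators are correct for
von Mises-like heading streams, not that real trajectories are von Mises.

**Spike trains** (`gen_cell_sweeps`): rate(φ) = baseline + modulation·g(φ)
with g a unit-peak von Mises shape (inverted for inhibited cells, axial
pair for bimodal; CCW modulation scaled to hit a target direction-
selectivity index); per-sweep preferred-angle jitter is Gaussian (default
σ = 5°); spikes are drawn by thinning a homogeneous Poisson process capped
at 2× the peak rate (exact for bounded rates).  Defaults: baseline 2 Hz,
peak modulation 18 Hz, κ = 3, 3 sweeps per direction, 36°/s, 5 s
pre-stimulus (inhibited cells default to a 25 Hz baseline with a 22 Hz
trough, since a deficit is only measurable against a high baseline).  Not
emulated: refractoriness, adaptation, bursting, slow drift of excitability.

**Star fields** (`gen_starfield`): Gaussian-profile stars (σ 1–3 px,
rejection-sampled positions with a minimum separation so the planted truth
is unambiguous) plus a Gaussian stripe through the centre (the bright
extended band), on a background solved iteratively so the global mean hits
the target (default 62) within ±1 level after clipping to [4, 255].
Default size 256×256 (image size is a free generator parameter; this scale
keeps the full test suite fast).  Not emulated: realistic stellar
magnitude distributions, projector gamma, vignetting.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 10 000 Monte-Carlo replicates
for Moore-test calibration (n = 20 vectors), 5 000 for the MWW and LR
calibrations, 200 populations per true mean (40 moths × 1 500 samples) for
behavioural recovery, 100 model neurons per response category for
classification recovery, and one 256² star field for the stimulus
contracts.  Optimizer: Nelder–Mead on (μ, log κ, logit λ) with moment-based
initialization; model fits are evaluated on 360-bin histograms, making a
full six-model selection a few milliseconds.  Ties in ranks use average
ranks everywhere.  All stochastic procedures take explicit integer seeds
and are bit-reproducible.

## Known limitations

* Moore-test p-values are Monte-Carlo, so they are granular at 1/(reps+1)
  and never exactly zero; numerical agreement with table-based software is
  approximate by construction.
* AIC model selection on large spike counts has a nonzero false-tuning
  rate; the response screen reduces it to roughly its nominal 5–10% but
  cannot eliminate it.
* The inhibited-cell deficit likelihood treats per-bin deficits as counts;
  its absolute AIC values are not comparable across response signs, only
  within a cell.
* The half-width bootstrap assumes the selected unimodal model is adequate;
  for strongly contaminated cells the IQR of the fitted component can
  differ from a nonparametric width.
* The direction-selectivity threshold (0.3) and the bimodal balance
  threshold (0.3) are explicit, configurable stand-ins for what was a
  qualitative judgement; cells near those boundaries are genuinely
  ambiguous.
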