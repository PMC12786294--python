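# Methods

`punctakit` quantifies live-cell fluorescence recordings of labeled DNA
loci: diffraction-limited puncta marking genomic sites (or
extrachromosomal DNA) inside a nucleus, imaged as 2D time-lapse stacks.
This note records the models, the parameter choices that matter, and the
limits of what the synthetic validation shows.

## Synthetic data model

Because raw recordings of this kind are rarely deposited, every estimator
in the package is validated against a generator that emits data together
with its exact ground truth.

**Images.** A frame is a constant nuclear background (an ellipse at
`background_level`, dimmer outside by `outside_fraction`) plus one
isotropic 2D Gaussian per punctum (amplitude above background, SD
`psf_sigma`), followed by an optional Poisson photon stage
(`photon_scale` photons per intensity unit) and additive Gaussian read
noise. Defaults: 128×128 px, 0.1 µm/px, 0.2 s/frame, 50 frames —
a typical high-frequency confocal acquisition of labeled loci. All
randomness flows from a single integer seed; identical configurations are
bit-identical.

**Motion.** A punctum's displacement is the sum of independent
components, so component MSDs add:

* *Brownian(D)* — i.i.d. Gaussian steps of variance `2 D Δt` per axis.
* *Confined(σ_s, τ)* — a discrete Ornstein–Uhlenbeck process per axis
  with the exact update
  `x ← μ + (x − μ) e^(−Δt/τ) + σ_s √(1 − e^(−2Δt/τ)) N(0,1)`,
  started from the stationary distribution. Its 2D MSD is
  `A (1 − e^(−t/τ))` with `A = 4 σ_s²` at *every* lag, which is why OU
  confinement is used rather than reflected diffusion in a disc (no
  closed-form MSD, so no exact oracle).
* *Directed(v, heading)* — deterministic drift, MSD `v² t²`.
* *Hopping* — OU confinement whose anchor jumps a fixed distance at a
  Poisson rate, emulating intermittent locus translocation.

**FRAP.** Three-phase series: pre-bleach frames at the baseline, one
bleach frame at `bleach_depth × baseline` (default 0.3 — the protocol
target of bleaching to ≈30% of baseline), then recovery
`baseline (b + m (1−b)(1 − e^(−k t)))` with mobile fraction `m` and rate
`k`. ROI and reference decay by a common per-frame acquisition-bleaching
factor; the background trace is constant. Default schedule: 2 pre-bleach
frames at 3 s, 61 post-bleach frames over ~180 s.

**Dual-channel puncta.** Each punctum binds `n` nanobodies; red intensity
is `2 n b_red (1 + ε)` and green `6 b_green (1 + ε′)` with independent
relative noise of CV `noise_cv` — two red fluorophores per bivalent
nanobody, six green per anchoring complex. An optional per-punctum spread
(`count_sd`) reproduces population variability in the bound count.

**What the generator does not emulate:** optical aberrations and 3D PSFs,
camera-specific gain (EMCCD excess noise), photoblinking/photobleaching
of individual fluorophores, intranuclear background structure, and
nuclear movement or deformation. Passing tests therefore demonstrate
correctness of the estimators under the stated statistical model, not
robustness to every artifact of real microscopy.

## Detection and counting

The blob detector filters with a scale-normalized, sign-corrected
Laplacian of Gaussian at `σ = d/(2√2)` for object diameter `d` (default
5 px), takes 8-connected local maxima above a quality threshold (quality =
LoG response magnitude), and refines positions by a quadratic fit to the
3×3 response neighborhood, clamped to ±0.5 px per axis. The threshold is
deliberately a required analysis choice, not a tuned default.

Foci counting rescales ROI intensities to 8-bit by the ROI min–max
(making the count invariant to gain and offset), thresholds (Otsu or
fixed), splits touching foci by a distance-transform watershed seeded
from distance-map maxima with a minimum seed separation, labels
components, filters by area, and discards anything touching the ROI
boundary — only fully contained foci count.

## Tracking

Frame-to-frame linking is an optimal bipartite assignment on squared
displacement (Jonker–Volgenant), with birth/death alternatives priced at
the gate cost; the gate is 5 px and is *not* widened while bridging gaps
(up to 5 frames; a longer absence splits the track into two particles).
Greedy nearest-neighbor linking was rejected as order-dependent. Bridged
frames are never interpolated into analysis samples.

## MSD analysis

Per-track MSD is the time average over all sample pairs at each lag;
pairs spanning a bridged detection gap are excluded. Ensemble curves are
unweighted per-lag means across the tracks reaching that lag, reported
with cross-track SEM and contributing-track counts (fewer tracks reach
longer lags — the usual source of tail noise).

The motion model fitted is

    MSD(t) = A (1 − e^(−t/τ)) + 4 D t + v² t²

with all parameters bounded non-negative. Initialization: A₀ from the
last-quartile mean of the fitted range, τ₀ from the first lag reaching
(1 − 1/e) A₀, D₀ from the initial slope, v₀ = 0. The reported effective
diffusion coefficient is **defined** as `D_eff = A/(4τ)` and holds
exactly in every emitted fit; the fitted linear coefficient is kept
separately as `linear_D`. Fits default to the first 25% of lags
(configurable): MSD tails are dominated by few pairs and statistical
artifacts, and truncation is the standard mitigation. Residuals are
weighted by 1/SEM when the curve carries one (inverse-variance
weighting), else by √n_pairs; on noise-free curves the solution is
unchanged. A localization-error offset term is intentionally absent from
the model; localization noise enters validation through simulation
instead.

The acceptance runs fit ensembles of 20 tracks × 50 frames with
`fit_fraction = 0.5`: at τ = 1 s the first half of the ~10 s curve spans
both the plateau rise and the plateau, which a quarter-curve fit only
marginally does.

## FRAP analysis

Double normalization:

    N(t) = (ROI − BG)/(REF − BG) × (mean_pre(REF) − mean_pre(BG))/(mean_pre(ROI) − mean_pre(BG))

which corrects acquisition bleaching (via the reference) and offset (via
the background) and anchors the pre-bleach mean at exactly 1 for
noise-free data. Bleach-pulse frames are excluded from the curve as
instrument artifacts, but their normalized value is retained to anchor
the recovery fit: the single-exponential
`N(t) = N_b + (plateau − N_b)(1 − e^(−kt))` cannot identify the
post-bleach floor `N_b` from post frames alone when recovery is fast, so
`N_b` is fixed to the normalized bleach-frame value when available and
fitted otherwise. `mobile_fraction = (plateau − N_b)/(1 − N_b)`.

## SNR

    SNR = (max intensity in the spot region − mean background) / SD background

with background pixels from `n_circles` (default 10) non-overlapping
circles of configurable radius, rejection-sampled under a seed fully
inside the nucleus and outside all punctum masks. The maximum is read
from the raw image — no smoothing — because pre-filtering would silently
change the statistic. SNR is invariant under positive affine intensity
maps, and a fixed seed reproduces the circle placement bit-exactly.
Cohorts aggregate as mean ± SD over puncta. Circle count and radius are
explicit configuration (no canonical values exist) and are logged.

## Nuclear positioning

For a spot inside a polygonal nuclear boundary, `L` is the shortest
distance to the boundary and `D` the centroid-to-boundary distance along
the ray through the spot; the ratio L/D is 0 at the periphery, 1 at the
centroid, and equals `1 − r/R` exactly on circles. The ray construction
(rather than the centroid's nearest-boundary distance) is what keeps the
ratio in [0, 1] and makes peripheral vs interior cohorts ordered as
expected. Non-convex outlines: the first intersection beyond the spot is
used and multi-crossing cases are flagged; outlines whose centroid falls
outside the polygon are rejected with a request for a star-shaped or
convex boundary. Mask-derived boundaries are polygonized at pixel
resolution and decimated at 0.5 px tolerance to stabilize intersections.

## Occupancy

Per punctum, the bound-nanobody count is `n = s (I_red/I_green)/c` with
`c` the mean red/green ratio of a 1:1 fusion standard (a ratio mean, not
a regression slope — robust at small n) and `s = 6/2 = 3` by default.
The rate is `100 · mean(n) / tags_per_anchor` (16 or 24). Estimates are
documented as lower bounds (green labeling of the anchor is itself below
100% efficient); means above the tag count are flagged, never clipped.
Inputs must be background-subtracted intensities.

## Problem sizes and numerical choices

Validation runs use ensembles sized to the study design they emulate —
20 tracks × 50 frames × 0.2 s per replicate, 100 replicates for
parameter-recovery statistics, 1000 puncta at 20% CV for the occupancy
round trip, 45/20-punctum cohorts for SNR summaries. Monte-Carlo
assertions use 3-SE bands (closed-form MSD agreement) or 2-SE bands
(round-trip recovery). Nonlinear fits use `scipy.optimize.least_squares`
(trust-region reflective, bounds at zero, xtol/ftol 1e-14); exact-tie
link assignments resolve by input order; degenerate inputs (flat
background, empty ROIs, single-sample tracks, non-positive reference)
raise rather than return silent values.

## Known limitations

2D only (detection, tracking, positioning); no Kalman/motion-model
prediction in linking; no diffusion-equation FRAP models (binding
kinetics only); no machine-learned spot classification; the generator's
noise model is Poisson–Gaussian without camera gain structure. The
fitted-model redundancy between `linear_D` and `D_eff = A/(4τ)` is
resolved by reporting both rather than choosing one.
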