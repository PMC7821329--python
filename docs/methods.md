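# Methods

This note documents the models, estimators and design choices behind
memclust, and what the synthetic-data generators do and do not emulate.
Units are µm, s and AU (arbitrary fluorescence units) throughout.

## Cluster quantification

**Segmentation.** `segment_membrane` offers three threshold policies.
The default, Otsu's bimodal split, is reproducible without hand tuning;
a guard returns an empty mask when the split does not clear the noise
floor (threshold within 2 robust SD of the median), so a blank
background field does not segment as half-foreground, while an exactly
constant image raises a degenerate-input error. The `half_max` policy
(background median plus half the background-to-peak span) matches the
full-width-at-half-maximum convention under which cluster areas are
defined, and is the policy used when areas must be compared to planted
truth; Otsu lands at an arbitrary point on a Gaussian blob's flank and
cannot guarantee FWHM-accurate areas. Every computed threshold is
logged at INFO.

**Detection and size classes.** Connected components use
8-connectivity; area = pixel count × pixel_size². Size bins are
left-closed/right-open — tiny (0, 0.2), small [0.2, 0.6),
medium [0.6, 1.0), long [1.0, ∞) µm² — giving a total, deterministic
classification; the bin edges are exercised explicitly in tests.

**Clustering index.** Implemented as the coefficient of variation
(population SD / mean) of membrane-pixel intensities per cell. A
condensed signal concentrates fluorescence into fewer, brighter pixels
at fixed total intensity, widening the intensity distribution and
raising the CV; the index is zero iff the signal is uniform and is
invariant to uniform intensity rescaling, which makes it comparable
across imaging sessions with different gain. A variance/mean (Fano)
estimator is available behind the `estimator` switch for users who want
a scale-bearing dispersion. Absolute index values depend on this
estimator choice; only orderings between conditions are meaningful.

**Outside confidence.** The mock interval is the empirical 2.5–97.5
percentile range of the pooled mock values (n ≥ 40 enforced), not
mean ± 1.96 SD: membrane intensity distributions are right-skewed, and
only the value-interval reading yields the 5% baseline for individual
pixel values under the null. The parametric variant remains selectable.

**Per-cell pooling.** Statistics are designed to be computed per cell
ROI and then pooled across cells, matching how replicate counts are
reported in practice.

## Single-particle tracking

Spot detection finds local maxima above background + `snr_min` × robust
noise (MAD-based, default snr_min = 5, chosen so pure-noise frames yield
no detections), then refines each to a sub-pixel centroid over a window
of ±max(3, 2.5 r) pixels — the window must cover the spot tails, or
truncation biases the centroid toward the window centre. Total
intensity is the background-subtracted window sum.

Linking is greedy nearest-neighbour within `max_disp`, with up to
`max_gap` missing frames, each detection used at most once. Greedy
association is exact in the single-particle limit and adequate at the
low densities the generators produce; it is not a global assignment and
will mis-link crossing particles.

The MSD is the time-averaged squared displacement per track, averaged
across the tracks of an ROI, with the SE across tracks reported. The
diffusion fit is a weighted (1/SE²) least-squares line over the first 4
lags by default and never more than a quarter of the track length — the
standard bias–variance compromise for short-lag D estimation. D =
slope/4 (2-D); a negative slope is clipped to D = 0 and flagged.
Static localization error of SD σ per axis inflates every measured
displacement independently of lag, offsetting the 2-D MSD by 4σ²; the
fit intercept therefore estimates 4σ² and is reported, not discarded.
Tracks with D below 10⁻³ µm²/s count as the immobile population where
one is needed; intensity classes use fixed boundaries low < 5×10³ ≤
medium ≤ 15×10³ < high (AU), resolving the overlap of the printed
ranges at the boundaries in favour of the middle class.

## FRAP

Curves are normalized to (I − background)/(prebleach − background), so
the pre-bleach plateau is 1; normalization is idempotent. The recovery
model is a single exponential, I(t) = I₀ + (I∞ − I₀)(1 − e^(−kt)),
fitted by bounded least squares with data-derived initial guesses
(first post-bleach value, tail mean, log 2 / half-recovery time).
Mobile fraction = (I∞ − I₀)/(1 − I₀), clipped to [0, 1]; stable = 1 −
mobile, exactly. A single-component model suffices for a mobile/stable
dichotomy; a multi-component fit is deliberately out of scope.

Precision at realistic noise is information-limited: with 5%-of-plateau
noise on one curve, the rate k of a fast, shallow recovery carries
~10–20% uncertainty regardless of estimator (most samples constrain
only the plateau). Recovery benchmarks therefore fit the mean of 100
replicate noisy curves — the ensemble-averaged design FRAP experiments
use in practice — where residual errors are a few percent.

## Kymographs and lifetimes

Kymographs are sampled along a polyline at 1-px arc-length steps with
bilinear interpolation, taking the maximum over `width` pixels
perpendicular to the local direction so a punctum slightly off the line
is not lost. Lifetimes are contiguous supra-threshold runs per spatial
row: duration = inclusive frame count × frame interval, so a streak
spanning frames 0–69 at 0.3 s is 21.0 s. One particle per row is
assumed at analysis densities; separate visits split at sub-threshold
gaps of ≥ 1 frame. Runs touching the first or last frame are censored
and excluded from summary means (their true lifetime is only bounded
below); Kaplan–Meier estimation would be the natural extension but the
simple uncensored mean matches how residence charts are reported.

## Asymmetry and gravitropism

Profiles are sampled like kymograph lines (1-px steps, bilinear,
mean across width). The sided ratio is mean(lower)/mean(upper); fold
change is treated/control and is scale-invariant. Angles are stored as
signed deviations from the vertical growth vector (positive toward the
gravity vector after reorientation); summaries default to absolute
deviations, the conventional bending magnitude. Group comparison is the
two-tailed pooled-variance Student's t-test; extraction of angles from
raw images is out of scope (the module consumes angle tables).

## Synthetic data

Generators are pure functions of their spec (seed included): identical
specs give bit-identical output, and planted ground truth is stored
alongside the rendered data.

- **Cluster fields.** Clusters are Gaussian-profiled blobs whose area
  is defined at half maximum (σ = √(area / 2π ln 2)), so thresholding
  at half maximum recovers the planted area; centres are
  rejection-sampled with centre distance ≥ 2 × the summed half-maximum
  radii (bounded retries, with an explicit error naming the density
  limit when the field cannot host the request). Peak intensity is
  common to all clusters, which makes a single global half-max
  threshold area-faithful.
- **Trajectories.** Free tracks take Gaussian steps of per-axis
  variance 2·D·Δt and reflect at the field edge; immobile tracks jitter
  only by the localization SD, which is added to every reported
  position. The default field is 20 µm (a realistic TIRF field of
  view); reflection suppresses long-lag MSD by ~σ_lag/L, so closed-form
  MSD benchmarks use a much larger field where the bias is negligible.
  Mean spot intensity is assigned per mobility class, mirroring the
  brighter-oligomer/less-mobile phenomenology, so intensity–mobility
  correlations can be reproduced by construction.
- **FRAP curves** follow the fitted model exactly plus optional
  Gaussian noise — self-model recovery is therefore a numerical test,
  not a model-adequacy test.
- **Kymographs.** Each particle occupies one row for one span. A
  lifetime drawn longer than the movie runs to the last frame and is
  censored; otherwise the span is placed uniformly over interior start
  frames, so uncensored ground-truth durations are an essentially
  unbiased exponential sample (placing starts uniformly in time and
  truncating would length-bias the uncensored mean low by ~10% at mean
  8 s in 90 s movies). At mean 8 s the exponential truncation loss is
  negligible.
- **Root fields** are two parallel bands whose noise-free means differ
  by the imposed fold.
- **Camera noise** is Poisson shot noise (scaled per-AU) followed by
  additive Gaussian read noise; both optional so tests can run
  noise-free. Real cameras' noise statistics for the emulated
  instruments are unknown; defaults are chosen for testability.

What the generators do **not** emulate: optical point-spread functions
and Airyscan processing, photobleaching, uneven illumination, cell
geometry, motion blur within a frame, or anomalous diffusion. Passing
tests therefore demonstrate correctness of the estimators on data
matching their assumptions, not robustness to every real-data artefact.

## Statistical design of the benchmarks

Stochastic recovery tests fix their seeds. A correct estimator compared
to truth in units of its own standard error is a ~standard-normal
statistic, so a "within 1 SE at every lag" check would reject correct
code about a third of the time; the benchmarks use 2·SE (the
conventional error-band reading) and representative fixed seeds, and
the problem sizes (500–1000 tracks, 1000 clusters, 200 lifetimes,
10,000-sample confidence calibration) keep sampling error well inside
the stated tolerances. Percentage-point tolerances (e.g. ±1.5 pp on the
5% baseline) are several multiples of the binomial SE at those sizes.

## Known limitations

Greedy linking degrades when particles cross; the clustering index is
one of several defensible dispersion estimators, so only within-study
orderings are comparable; censored lifetimes are dropped rather than
survival-modelled; FRAP assumes a spatially uniform bleach with no
reaction–diffusion correction; absolute intensities are arbitrary units
with no photon calibration.
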