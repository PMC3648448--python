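# Methods

This note documents the models, conventions and design choices behind
`petgate`, in the order data flows through the package.

## Synthetic acquisitions

The simulator emulates a rat-scale PET acquisition and provides the
ground truth all tests are judged against.

**Breathing waveform.** Cycle periods are i.i.d. truncated normal
(mean 1.0 s by default — rat breathing is ~1 Hz — SD 0.05 s, truncated at
±50% of the mean so no non-physical cycles occur).  Phase advances
linearly from 0 to 1 within each cycle.  Real rodent breathing has
inspiration/expiration asymmetry, apnea pauses and amplitude drift; the
generator reproduces only quasi-periodicity with period jitter, which is
the property the trigger logic must tolerate.

**Phantoms.** Scenes are ordered lists of analytic shapes (ellipsoids,
boxes) with absolute activity concentrations, painted in order; moving
structures carry a periodic trajectory in phase.  Two stock scenes:

* *rat phantom* — an elliptical body (activity 1), a liver compartment
  (activity 4) and an embedded hot lesion (activity 8) translating
  axially with a sinusoidal 3 mm peak-to-peak excursion, emulating
  diaphragm-driven motion;
* *moving-lesion scene* (2D, 64×64, 1 mm pixels) — uniform background 1,
  a stationary two-compartment boundary (activities 1.5 and 3.0), and an
  8 mm circular lesion (activity 3) moving sinusoidally left–right with
  peak-to-peak displacement 0.6 × diameter.

**Event sampling.** Emission is an inhomogeneous Poisson process with
per-voxel rate proportional to the activity at the instantaneous phase;
the realized total is Poisson(expected counts).  Phase is discretized to
32 activity grids and time to 10 ms steps — both much finer than the
100 ms analysis binning.  Each event carries its origin voxel and a
sinogram coordinate from a simplified projector: a uniformly random
azimuth per event, the radial bin from the voxel's signed transaxial
distance along that azimuth, and the SSRB slice equal to the axial voxel
index.  This preserves spatially localized count fluctuations — all the
trace extraction uses — without modeling detector physics (no
attenuation, scatter, randoms, or depth effects).

**Idealized reconstruction** histograms origin voxels (optional Gaussian
smoothing of stated FWHM).  Counts are exact and the gate-partition
identity holds with zero tolerance; what this deliberately does *not*
exercise is tomographic reconstruction error, which is orthogonal to the
gating and filtering logic under test.  Consequently, passing tests show
the *algorithms* behave as specified under Poisson statistics; they do
not certify behavior under reconstruction artifacts.

Simulation studies use a reduced geometry (8 rings → 15 SSRB slices,
32 radial bins × 16 angles, 32×32×15 voxels of 1 mm) with the same
invariants as the full 80-ring, 128×160×159 geometry; study sizes
(10^6–10^7 events per simulated scan, 100 realizations per count level,
10^4 interpolation simulations, 10^6 threshold draws) were chosen as the
smallest at which the reported statistics are stable across seeds.

## Trace extraction

* Short-time bins: 100 ms, about one tenth of a breathing cycle.
* Regions are 4 (ρ) × 4 (θ) × 1 (z) sinogram blocks — a compromise
  between SNR per region and spatial locality; block size is a config
  key.
* Each region trace is detrended by subtracting a 10 s moving mean
  before spectral scoring, so tracer-kinetics drift (e.g. FDG uptake)
  cannot leak power into the low-frequency end.
* Score = (non-DC power inside 0.66–3.33 Hz) / (total non-DC power),
  from a plain magnitude-squared DFT of the detrended trace, no taper.
* The global trace starts from the z-scored top region; each further
  candidate among the top 10% by score is added (sign-flipped as needed)
  only if the sign of its zero-mean correlation with the running
  reference agrees in all six equal time segments.  Z-scoring prevents
  high-count regions from dominating; the acceptance quota and segment
  count are config keys.  The trace's overall sign is arbitrary.

## Triggers and gating

Candidate triggers are local maxima of the trace (plateaus contribute
their leftmost sample) after band-limiting to the respiratory window —
the trace's signal content by construction — so bin-level noise cannot
split a breath crest into several maxima.  Candidates are pre-separated
by half the dominant spectral period; the most-represented period is the
mode of the candidate-interval histogram (100 ms bins centered on
multiples of 100 ms, ties toward the shorter period), and conflicting
peaks closer than half of it are resolved by keeping the higher one.
Trigger times are bin centers, so timing resolution is the 100 ms bin.

Gating divides each complete trigger-to-trigger cycle into 16
equal-duration phase bins.  Events before the first or after the last
trigger, and cycles shorter than one clock tick per gate, are discarded
and logged; no other cycle-length rejection is applied, and gates bin raw
counts (no weighting by cycle count or duration).  Random triggers
permute the respiratory inter-trigger intervals and lay them down from a
uniformly random offset in [0, first interval): the interval multiset —
hence per-gate count statistics — is preserved while the phase relation
to motion is destroyed.  Two gatings of the same stream therefore assign
each voxel the same total counts, which is what makes the noise
comparison meaningful; image-space simulations reproduce this coupling by
re-partitioning each voxel's realized total uniformly over gates rather
than drawing an independent realization.

## The gating+ filter

Transform convention: one-sided real-input DFT with 1/N forward
normalization, so `c_0` equals the gate mean, conservation is a statement
about `c_0` alone, and the inverse transform is exact to float precision.

* Effective noise = max over k ≥ 1 of the randomly gated `|c_k|` — one
  conservative scalar per voxel, applied at every frequency.
  Per-frequency noise estimates are a deliberate non-choice: the maximum
  mirrors the definition of the published method and makes the no-motion
  null conservative.
* Cutoff `k*` = the longest run `k = 1..K` with `|c_k| > 1.2 × noise`.
  Anchoring the run at the fundamental means no high frequency passes
  without all its supporting lower frequencies, which prevents isolated
  noise spikes and Gibbs-like jumps.  An interior-band alternative (runs
  not anchored at k = 1) was considered and rejected as physically
  unmotivated for breathing harmonics.
* Gated coefficients above `k*` are zeroed; the inverse transform may
  produce negative gate values when passed fluctuations exceed the voxel
  mean.  They are reported (fraction, total negative mass), never
  clipped.
* The motion map is the integer `k*` per voxel (optionally in Hz via
  k / breathing period).  CMI frames evaluate the retained spectrum at
  phases j/n_frames as `c_0 + Σ 2·Re{c_k e^(+2πikφ)}` (Nyquist term not
  doubled); at the N gate phases this reproduces the filtered gates to
  1e−9, which the suite asserts.

One phase-alignment subtlety: the DFT anchors gate g at phase g/N, while
a gate's value physically represents its bin *center* (g + ½)/N.  The
interpolation-accuracy experiment evaluates the CMI curve with that
half-gate shift when comparing against continuous ground truth; CMI
frame indexing itself keeps the DFT convention.

## The 1.2 threshold

A gated coefficient is `s = m + n`: true motion vector `m` plus noise
`n`.  Keeping `s` (error `|n|`) beats discarding it (error `|m|`) exactly
when `|n| < |m|`.  Noise in a DFT coefficient of counting noise is a
complex Gaussian vector: phase uniform, magnitude Rayleigh.  Measuring
magnitudes in units of the modal (most probable) noise magnitude — the
Rayleigh scale σ — the keep-better probability at motion-to-noise ratio
R is the Rayleigh CDF `1 − exp(−R²/2)`, which crosses ½ at the Rayleigh
median `√(2 ln 2) ≈ 1.177` — the "approximately 1.2" break-even — with
P(1.2) = 0.513.  `calibrate_threshold` estimates this curve by Monte
Carlo: R ~ Uniform(0, 4) (the prior maximum is a config key and the
break-even is insensitive to it, since the curve is conditional on R),
noise drawn as a unit-scale complex Gaussian, draws binned at width 0.01.
Antithetic Rayleigh magnitudes (inverse-CDF pairs u, 1−u sharing R)
reduce the binomial variance of the per-bin fractions severalfold at no
cost in expectation.  The crossing search smooths the curve over 5 bins
(count-weighted) so a single noisy bin cannot fake a crossing, then
interpolates linearly; probability queries at a given ratio use a
bin-width window centered on the query (snapped to a half-bin grid),
which avoids the half-bin bias of a floor-grid bin when the query — like
1.2 — lies exactly on a bin edge.  A fixed-unit-magnitude noise variant
(`noise_model="fixed"`) and observed-ratio binning
(`binning="observed"`) are available for comparison; the fixed-magnitude
model is degenerate (a step at R = 1) and the observed-ratio curve
crosses ½ near √2 rather than 1.2.

## Validation metrics

* COM uses plane sums with voxel-center coordinates (0-based index ×
  pitch) over the full grid; a body mask is intentionally not applied.
  Negative values (post-filter) enter algebraically; the total must stay
  positive.
* The random-gating envelope orders points by scan counts and takes a
  centered moving mean + 2 moving SDs over 9 points (window config-
  exposed; edges use shrunken windows).  With a 9-point window the ±2 SD
  coverage carries noticeable small-sample bias, so the Gaussian-tail
  check in the suite uses a wide window where the nominal ~2.3%
  exceedance applies.  The single-scan pipeline adapts the idea: the
  respiratory-gated max COM displacement is compared against mean + 2 SD
  of the max COM displacements of 20 independent random gatings of the
  same stream.
* VOI membership is voxel-center-in-sphere (radius from volume and voxel
  size); partial-volume weighting was rejected for testability.  %SD is
  100 × SD/mean of the per-gate VOI-mean series.
* Line profiles sample trilinearly; the boundary is the first crossing of
  50% of the profile maximum (level config-exposed); FWHM interpolates
  the half-maximum crossings around the peak with the profile minimum as
  baseline.

## Count-level and accuracy studies

The moving-lesion study draws Poisson gate images at
`level × 500` expected events per gate (levels 1, 4, 13, 55, 2000; the
absolute scale is a declared config choice — published tables of this
kind do not define their noise scale, so all comparisons are internal
orderings and limits, not absolute cell values).  The filter runs on raw
counts; metric images are then smoothed with a 2-pixel-FWHM Gaussian
(the reconstruction-style filter) and expressed in counts per expected
gate total so levels are comparable.  Metrics for the gated and gating+
conditions are averaged over all 16 gates, each measured at its own
lesion position.  The characteristic pattern: at the lowest level the
per-voxel series are so sparse and discrete that essentially nothing
beats the coupled noise estimate, so gating+ collapses to the (low-noise,
motion-blurred) ungated behavior; at the highest level everything passes
and gating+ reproduces the gated values; in between it trades smoothly.

`accuracy_probability` reports, per voxel, the fraction of realizations
in which the gating+ value is closer to the noiseless truth than the
ungated value.  Two comparators exist because they answer different
questions.  Against the *same-realization gate mean* (ungated/N), a
static voxel whose filter collapses to DC is an exact tie (counted ½, with
a float tolerance for the inverse-FFT residue), and occasional spurious
passes make static background P slightly below ½ — so this comparator
isolates where motion recovery helps.  Against an *independent
count-equivalent ungated realization* (single-gate statistics, as in
side-by-side image comparisons), gating+ also enjoys its 16-fold DC
statistics advantage, and P exceeds ½ in essentially every voxel.

Comparison filters: ramp (gain falling linearly from 1 at DC to 0 at the
gate Nyquist, voxel-independent) and a per-voxel Wiener gain
`max(|c_k|² − |N|², 0) / |c_k|²` with |N| the effective noise.  Both keep
DC and hence conserve per-voxel sums.

## Known limitations

* The projector and idealized reconstruction ignore attenuation,
  scatter, randoms and detector blur; absolute SNR in simulations is
  optimistic.
* Phase binning only; amplitude-based gating is out of scope.
* The filter is all-or-nothing per frequency; partial (Wiener-style)
  attenuation combined with the random-gating noise estimate is a known
  extension, implemented here only as a comparison arm.
* The envelope classification at rat-population scale requires many
  scans of varying counts; the package provides the machinery and its
  single-scan adaptation, validated on simulation only.
* Gated cycle bookkeeping discards partial edge cycles; scans whose
  trace finds no consistent regions fail loudly at the extract-trace
  stage rather than guessing.
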