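# Methods

This note documents the models, numerical choices, and simulation
conventions behind `prfmap`, and what the synthetic benchmarks do and do not
establish about real data.

## Stimulus apertures

Aperture movies are binary masks on a square grid of cell centers spanning
[-fov, +fov] degrees per axis, one mask per acquisition volume (TR = 3 s).
The grid is odd-sized (101 x 101 by default) so a cell center sits exactly at
fixation; cell membership is decided by the cell-center coordinate.
Coordinates: x rightward, y upward, polar angle counter-clockwise from
3 o'clock.

* **Wedge runs**: a 36-degree wedge stepping 18 degrees per volume
  (20 volumes = 60 s per cycle). The leading edge starts at 90 degrees
  (12 o'clock) by default and is configurable; clockwise and anticlockwise
  movies are frame-order reverses of each other within a cycle, up to the
  start convention.
* **Ring runs**: ring mid-radii are log-spaced from an inner radius
  (default 0.28 degrees, one grid cell beyond the fixation dot — the
  smallest ring radius is not part of the printed design) to the field
  radius; each ring covers the annulus between the geometric midpoints to
  its neighbors, so the steps tile eccentricity without gaps or overlap.
* **Full-field runs**: the whole stimulated disk for one volume, then blank
  for nine (30 s trials, 10 trials).
* **Session presets**: session 1 is wide-field (37.5-degree radius; 8 wedge
  cycles or 16 ring steps x 10 repetitions; 20 end-of-run blank volumes;
  3 initial dummy volumes; 183 volumes = 549 s per run). Session 2 is
  narrow-field (9 degrees; 3 cycles or 12 steps x 5 repetitions; 15 blanks;
  78 volumes = 234 s). The session-1 wedge cycle count is inferred as the
  unique integer reproducing the printed run length. Runs are homogeneous
  (wedge-only or ring-only); both decompositions reproduce the printed
  totals, and mixed runs can be composed by concatenation.
* Fixation region and contrast-ramped annulus are treated as stimulated: a
  binary aperture cannot represent ramped contrast. This is a documented
  simplification with negligible effect at the default grid resolution.
* The scotoma-masked control model multiplies every frame by a keep-mask
  (e.g. upper-right quadrant only). Masking is idempotent; a mask that
  blanks the whole field warns but is legal.

## HRF model and estimation

The impulse response is a difference of two gamma-shaped lobes,
`h(t) = A [g(t; tau_p) - g(t; tau_u)/ratio]`, where
`g(t; tau) = (t/tau)^kappa exp(kappa (1 - t/tau))` has fixed shape
kappa = 6 and unit peak exactly at its latency parameter. The four free
parameters are amplitude, peak latency (default 5 s), undershoot latency
(15 s) and peak/undershoot ratio (6). This parameterization exposes exactly
the four quantities named above while keeping the kernel shape family
conventional; `h(0) = 0` and `h` is linear in amplitude.

Estimation: each vertex's full-field run is averaged across the 10 trial
repetitions (30 s windows); a vertex is "responsive" when mean minus SEM,
averaged over the first half of the trial window, exceeds zero (a stricter
per-volume variant is available — the averaged rule keeps valid noisy
vertices the per-volume rule rejects). The two-gamma is fitted to the grand
average over responsive vertices (optionally per hemisphere) by bounded
Nelder-Mead from the default parameters (peak in [2, 10] s, undershoot in
[8, 25] s, ratio in [1, 20] — the bounds prevent the lobes from swapping
roles), with one polishing restart. Because run-level z-standardization
gives event averages a negative DC offset that an offset-free kernel cannot
absorb, the grand average is shifted so its pre-stimulus volume is zero
before fitting.

Known bias: with 30 s trials and a 32 s kernel, each trial's undershoot
tail bleeds ~3 s into the next window, slightly inflating the fitted
undershoot ratio (by ~1 unit at zero noise). This is inherent to the event-
averaging design, affects predictions by well under 1% of variance, and is
why the zero-noise round-trip benchmark fits with the generating kernel
rather than a re-estimated one.

## pRF fitting

Predictions: per-volume overlap of the unit-peak Gaussian with the aperture,
convolved with the HRF sampled at TR (kernel truncated at 32 s, output
trimmed to run length), then z-scored to match the data. A constant overlap
(pRF outside every aperture, or stimulated identically in every frame) is
degenerate by definition — before convolution, so the convolution onset
transient cannot masquerade as signal.

Preprocessing mirrors the scanner-side convention: per run, drop the first
three volumes, remove a linear trend, z-standardize each vertex, concatenate
runs. Zero-variance vertices are flagged unfittable, never raised.

* **Coarse stage**: exhaustive search over a polar grid (15 angles x 12
  log-spaced eccentricities from 0.1 degrees to 1.5x the outer stimulus
  eccentricity x 8 log-spaced sigmas from 0.25 degrees to half that bound;
  grid density is a package convention), maximizing signed Pearson
  correlation; beta is ignored. Ties break toward the lowest candidate
  index; degenerate candidates score -inf. Run on smoothed data:
  neighbor-graph averaging when a vertex adjacency is supplied, else a
  width-3 temporal moving average as the stand-in for cortical-surface
  smoothing (a synthetic cortex has no geometry by default).
* **Fine stage**: Nelder-Mead over (x, y, log sigma) on the unsmoothed
  series (max 500 evaluations, parameter tolerance 1e-4; log
  parameterization keeps sigma positive; centers beyond the search bound
  are penalized). Beta is profiled analytically at each evaluation as the
  least-squares scale of the mean-centered HRF-convolved overlap against
  the z-scored data — mathematically the same optimum as searching beta
  explicitly, but better conditioned; the fitted beta is reported and
  negative betas flagged. The initial simplex is explicit (half a sigma in
  position, 0.3 in log sigma): the default simplex collapses for
  coordinates at zero and would pin meridian pRFs to the meridian.
* **Multi-start**: the characteristic failure mode of the fine objective is
  a sigma-collapsed local minimum near the stimulus edge. The surface
  driver therefore restarts the simplex from the best coarse candidate,
  from that candidate with sigma inflated 4x, and from the
  next-best-correlated candidate in a different basin (far in position or
  at a clearly different sigma scale), keeping the lowest-residual
  solution. Three starts recover every vertex of a 200-vertex zero-noise
  cortex exactly; one start misses ~1 in 200.

R^2 is 1 - SS_res/SS_tot against the z-scored series, clipped to [0, 1];
maps threshold at 0.05 by default.

## Maps, coverage, summaries

Polar angle in [0, 360) counter-clockwise from 3 o'clock; eccentricity in
degrees. Visual-field coverage is the pointwise sum of unit-peak Gaussian
profiles of (above-threshold) pRFs — unweighted by beta so the flatness of
coverage is scale-free; a beta-weighted variant and per-vertex
normalization are flags. Eccentricity-band summaries use half-open bands
(default: 9 equal-width bands up to the stimulus eccentricity) and report
mean and SEM per band; empty bands are missing (NaN), not zero, and
single-vertex bands have no SEM. Area labels (V1v..V3d) are supplied as
label tables; the synthetic cortex ships ground-truth labels, and automatic
map delineation is out of scope.

## Synthetic cortex

`make_ground_truth` tiles each hemisphere-by-area quadrant (left hemisphere
= right hemifield; dorsal = lower quadrant, ventral = upper) with centers
drawn area-uniformly over the quadrant disk (eccentricity = fov sqrt(u),
with a 5%-of-fov floor so no pRF sits inside the innermost ring), one
seeded draw per spec; a group reduced to a single vertex sits at its
quadrant center. Sigma grows linearly with eccentricity
(sigma = 0.5 + 0.1 ecc degrees for V1, scaled 1.5x for V2 and 2x for V3) —
synthetic conventions chosen to mimic the qualitative size-eccentricity
relation of early visual areas, not empirical claims. Real cortical maps
oversample the fovea (cortical magnification) and carry structured,
autocorrelated noise; the simulator does neither by default (iid Gaussian
noise in z units; an AR(1) option exists but is off), so passing benchmarks
demonstrate correctness of the estimation machinery, not performance on
scanner data.

Lesions silence the stimulus-driven signal of vertices whose *true* center
falls in a visual-field region while keeping their noise variance —
emulating absent response, not absent tissue. Detection scoring calls a
vertex "detected" when its fit falls below the R^2 threshold; sensitivity
is evaluated over lesioned vertices and specificity over intact ones.

### What the benchmarks show

With 200 vertices on the wide-field session design (two 183-volume runs,
41 x 41 aperture grid — benchmark sizes chosen to exercise the full design
at interactive cost):

* zero noise: every vertex's (x, y) recovered within 0.05 degrees, sigma
  within 5%, R^2 >= 0.999 — the forward model and fitting loop are exact
  inverses;
* noise 0.5 (z units; signal variance 1): median center error ~0.5
  degrees, but the RMSE (~1.5 degrees) is dominated by vertices near the
  37.5-degree field edge, where ring radii are log-sparse and sigma is 4-8
  degrees: there the maximum-likelihood optimum itself sits degrees from
  truth (verified by restarting at the true parameters), and position and
  sigma trade off beyond the stimulus border. On the narrow 9-degree field
  the same conditions give ~0.5-degree RMSE. Absolute-degree accuracy is a
  property of the design, not just the estimator;
* a pure-noise cortex stays below the 0.05 R^2 threshold (>= 95% of
  vertices), so the map threshold controls false positives at full run
  length;
* a 25% simulated cortical scotoma is detected with sensitivity and
  specificity above 0.9 and leaves a visible coverage hole. This is the
  linchpin: the pipeline *does* flag silenced cortex, so finding fully
  normal maps and flat coverage on intact input is an informative negative;
* fitting full-field-responsive cortex against an upper-right-only masked
  stimulus model displaces the majority of lower-left-truth pRFs out of
  their quadrant — reproducing the expected artifact pattern of a
  scotoma-masked control analysis, and confirming that normal maps cannot
  be an artifact of the mask.

## Behavioral computations

* Perimetry screen: 4 eccentricity rings (9.375-degree spacing to a
  37.5-degree outer radius) x 8 sectors x 2 repetitions (one
  stimulus-present, one absent) = 64 trials in seeded pseudo-random order.
  A position is intact only if its present trial was detected *and* its
  absent trial rejected; a single error marks it impaired (the source
  bookkeeping records only hits and false positives; the conjunction rule
  is this package's convention).
* Blindsight screen: BF01 for guessing (p = p0) against a uniform
  Beta(1, 1) alternative; two-sided closed form
  `(n+1) C(n,k) p0^k (1-p0)^(n-k)`, one-sided variants by restricting and
  renormalizing the prior via the incomplete beta function. Two-sided with
  a uniform prior is the default reading of a generic binomial Bayesian
  test; published per-run Bayes factors cannot be recomputed exactly
  without per-location trial counts, which are not printed.
* Staircases: n-down/1-up with a reversal recorded at the pre-change level
  on every direction flip. The size-ratio track steps 0.04 natural-log
  units until the fifth reversal and 0.02 after (the step that records the
  fifth reversal already uses the small size — a documented convention);
  the coherence track uses fixed +/-5% steps (+/-20% in the five-dot
  variant) bounded to [0, 1]. Simulated observers use logistic psychometric
  functions with configurable PSE, slope and lapse; 1-down/1-up reversal
  means converge to the observer's 50% point and 2-down/1-up to its 70.7%
  point.
* Illusion strength: reversals outside median +/- 2 MAD are discarded and
  the survivors averaged. MAD is unscaled (no 1.4826 consistency factor)
  and boundary values are kept, so identical reversals (MAD 0) survive.
  Positive values mean the small-inducer target is judged larger at
  physical equality. The physically-equal-pair control reports the choice
  proportion with a two-sided exact binomial p-value against 0.5.

## Interfaces

Aperture movies and volume series travel as NIfTI with JSON sidecars
(field radius, TR, frame labels); tables (truth, fits, maps, band
summaries, trial logs) as TSV with a header, joined on `vertex_id`; HRFs
and run manifests as JSON; pipeline configs as YAML. The `prfmap` CLI is a
thin wrapper over the library; `prfmap run` executes the synthetic
end-to-end pipeline (apertures -> simulate -> fit-hrf -> fit-prf -> maps ->
coverage -> report) and is bit-identical on rerun for a fixed config.

## Known limitations

Compressive spatial summation, difference-of-Gaussians pRFs, surface
geometry (smoothing uses a temporal stand-in without an adjacency),
cortical magnification in the simulator, and structured physiological noise
are all out of scope. Beta is identifiable only up to the data's
z-standardization scale. HRF estimation inherits the event-average tail
bias described above.
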