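# prfmap

Population receptive field (pRF) retinotopic mapping in Python: from stimulus
design to parameter maps, with a synthetic-cortex simulator that makes the
whole pipeline testable without scanner data.

## Who this is for

Vision scientists analyzing fMRI retinotopy — in particular the case where
the scientific question is whether cortical maps are *normal*: a patient with
perimetric visual-field loss can still show intact retinotopic organization,
and that negative finding is only meaningful if the pipeline demonstrably
*would* detect lost cortical function. `prfmap` therefore ships, alongside
the estimation machinery, a ground-truth simulator with optional "cortical
scotoma" lesions and recovery/detection scoring.

## The model

Each cortical vertex's population receptive field is a 2-D isotropic
Gaussian in visual-field coordinates,

```
g(u, v) = exp(-((u - x)^2 + (v - y)^2) / (2 sigma^2)),
```

with center (x, y) and spread sigma in degrees of visual angle, plus a
response amplitude beta. The predicted BOLD series is the per-volume overlap
between g and the binary stimulus aperture (rotating 36-degree wedge stepping
18 degrees per volume; expanding/contracting rings with log-spaced radii;
full-field on/off for HRF estimation), convolved with the subject's
hemodynamic response function — a two-gamma kernel with free amplitude, peak
latency, undershoot latency and peak/undershoot ratio, estimated from event
averages of a full-field run. Fitting is coarse-to-fine: exhaustive grid
search maximizing the Pearson correlation on smoothed data (beta ignored),
then a multi-start Nelder-Mead refinement of (x, y, log sigma) on unsmoothed
data with beta profiled out by linear least squares. Per-vertex results are
R^2-thresholded (default 0.05) and summarized as polar-angle/eccentricity
maps, visual-field coverage (the sum of unit-peak pRF profiles), and
eccentricity-band means of sigma, beta, and R^2.

The package also implements the behavioral computations used alongside
mapping: a 32-position computerized perimetry screen (4 rings x 8 sectors,
64 trials), a forced-choice blindsight screen scored with a binomial Bayes
factor (BF01 = (n+1) C(n,k) p0^k (1-p0)^(n-k) for the two-sided test),
adaptive 1-down/1-up and 2-down/1-up staircases with reversal bookkeeping,
and a robust illusion-strength estimator (mean of reversals within
median +/- 2 MAD).

## Worked example

```python
import numpy as np
from prfmap import *

# wide-field session design: one wedge + one ring run, 183 volumes each
wedge = make_session_run(1, "wedge", grid_n=41)
ring = make_session_run(1, "ring", grid_n=41)
movie = wedge.concat(ring)
print(movie.n_frames, run_duration_s(wedge))        # 366 549.0

# simulate a 60-vertex retinotopic cortex and fit it back
spec = SimulationSpec(n_vertices=60, fov_radius_deg=37.5, noise_sd=0.5, seed=1)
truth = make_ground_truth(spec)
data = simulate_timeseries(truth, movie, DEFAULT_HRF, noise_sd=0.5, seed=2)
fits = fits_to_frame(fit_surface(data, movie, DEFAULT_HRF),
                     vertex_ids=truth.vertex_id.to_numpy())
rep = recovery_report(truth, fits, threshold=0.05)
print(round(rep["position_rmse"], 2), round(rep["sigma"]["correlation"], 2))
```

prints `366 549.0` for the design check (366 concatenated volumes; each run
lasts 549 s) and then

```
1.18 0.94
```

— at noise 0.5 (z units) most pRF centers land well under a degree from
truth, the RMSE is dominated by poorly-constrained vertices near the
37.5-degree field edge, and fitted sigmas correlate strongly with truth. A
`behav` example:

```python
from prfmap import bf01_binomial, illusion_strength
bf01_binomial(5, 10)                        # 2.707: even evidence favors guessing
illusion_strength([0.18, 0.20, 0.22, 0.90]) # 0.20: the 0.90 reversal is MAD-filtered
```

A command-line interface mirrors the library
(`prfmap apertures|simulate|fit-hrf|fit-prf|maps|coverage|behav|run`); see
`prfmap --help`.

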