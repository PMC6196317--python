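"""Gaussian population receptive field (pRF) forward model and fitting.

A pRF is a 2-D isotropic Gaussian in visual-field coordinates with center
(x, y), spread sigma (all in degrees of visual angle) and response amplitude
beta.  The predicted BOLD series for a pRF is the per-volume overlap between
the Gaussian (unit peak at its center) and the binary stimulus aperture,
convolved with the subject's HRF sampled at TR resolution.

Fitting is coarse-to-fine: an exhaustive grid search maximizing the Pearson
correlation between prediction and (smoothed) data picks a starting
candidate while ignoring beta; a derivative-free simplex search then
minimizes the summed squared residuals against the unsmoothed data over
(x, y, log sigma), with beta profiled out analytically at each step (data
are z-standardized, so beta is the scale of the mean-centered HRF-convolved
overlap that best matches the data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .apertures import ApertureMovie
from .hrf import TwoGammaHRF, sample_kernel

__all__ = [
    "GaussianPRF",
    "fitted_prediction",
    "SearchGrid",
    "FitResult",
    "preprocess_timeseries",
    "gaussian_profile",
    "overlap_timecourse",
    "predict_timeseries",
    "grid_predictions",
    "coarse_fit",
    "fine_fit",
    "fit_surface",
    "smooth_temporal",
    "smooth_adjacency",
    "fits_to_frame",
]

_VAR_EPS = 1e-12
KERNEL_DURATION_S = 32.0


@dataclass(frozen=True)
class GaussianPRF:
    """2-D Gaussian receptive field model (degrees of visual angle)."""

    x_deg: float
    y_deg: float
    sigma_deg: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma_deg > 0:
            raise ValueError("sigma_deg must be positive")

    @property
    def eccentricity_deg(self) -> float:
        return math.hypot(self.x_deg, self.y_deg)


@dataclass(frozen=True)
class FitResult:
    prf: GaussianPRF
    r_squared: float
    stage: str  # coarse | fine
    correlation: float | None = None
    converged: bool = True
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class SearchGrid:
    """Candidate (x, y, sigma) triples for the coarse grid search.

    Candidates are enumerated position-major with sigma innermost; the coarse
    stage breaks correlation ties by this enumeration order.  ``max_ecc_deg``
    (1.5x the outer stimulus eccentricity) bounds pRF centers in both stages.
    """

    x: np.ndarray
    y: np.ndarray
    sigma: np.ndarray
    max_ecc_deg: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "sigma"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if not (self.x.size == self.y.size == self.sigma.size):
            raise ValueError("candidate arrays must have equal length")
        if self.sigma.size == 0:
            raise ValueError("search grid is empty")
        if (self.sigma <= 0).any():
            raise ValueError("sigma candidates must be strictly positive")

    @property
    def n_candidates(self) -> int:
        return self.x.size

    @classmethod
    def default(
        cls,
        stimulus_ecc_deg: float,
        n_angles: int = 15,
        n_ecc: int = 12,
        n_sigma: int = 8,
        min_ecc_deg: float = 0.1,
        min_sigma_deg: float = 0.25,
    ) -> "SearchGrid":
        """Polar default grid: log-spaced eccentricities and sigmas.

        max eccentricity is 1.5x the outer stimulus eccentricity; sigma runs
        log-spaced from ``min_sigma_deg`` to half the max eccentricity.
        """
        max_ecc = 1.5 * stimulus_ecc_deg
        angles = np.deg2rad(np.arange(n_angles) * 360.0 / n_angles)
        eccs = np.geomspace(min_ecc_deg, max_ecc, n_ecc)
        sigmas = np.geomspace(min_sigma_deg, 0.5 * max_ecc, n_sigma)
        xs, ys, ss = [], [], []
        for a in angles:
            for e in eccs:
                for s in sigmas:
                    xs.append(e * math.cos(a))
                    ys.append(e * math.sin(a))
                    ss.append(s)
        return cls(np.array(xs), np.array(ys), np.array(ss), max_ecc)

    @classmethod
    def cartesian(cls, xs, ys, sigmas, max_ecc_deg: float | None = None) -> "SearchGrid":
        """Explicit Cartesian product grid in (x, then y, then sigma) order."""
        xs, ys, sigmas = (np.asarray(v, float) for v in (xs, ys, sigmas))
        X, Y, S = [], [], []
        for x in xs:
            for y in ys:
                for s in sigmas:
                    X.append(x)
                    Y.append(y)
                    S.append(s)
        if max_ecc_deg is None:
            max_ecc_deg = float(np.hypot(np.abs(xs).max(), np.abs(ys).max()))
        return cls(np.array(X), np.array(Y), np.array(S), max_ecc_deg)


# ---------------------------------------------------------------------------
# preprocessing


def preprocess_timeseries(
    raw_runs, n_dummy: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize raw runs: drop dummies, detrend, z-score, concatenate.

    ``raw_runs`` is a sequence of (vertices x volumes) arrays.  Per run the
    first ``n_dummy`` volumes are discarded, a linear trend is removed from
    each vertex, and each vertex series is z-standardized; runs are then
    concatenated in order.  Zero-variance vertices are flagged unfittable
    (second return value), not raised.
    """
    runs = [np.atleast_2d(np.asarray(r, dtype=float)) for r in raw_runs]
    pieces = []
    unfittable = None
    for run in runs:
        run = run[:, n_dummy:]
        if run.shape[1] < 3:
            raise ValueError("each run needs >= 3 volumes after dummy removal")
        detr = signal.detrend(run, axis=1, type="linear")
        sd = detr.std(axis=1)
        bad = sd < _VAR_EPS
        sd_safe = np.where(bad, 1.0, sd)
        z = (detr - detr.mean(axis=1, keepdims=True)) / sd_safe[:, None]
        z[bad] = 0.0
        pieces.append(z)
        unfittable = bad if unfittable is None else (unfittable | bad)
    return np.concatenate(pieces, axis=1), unfittable


def _zscore(v: np.ndarray) -> tuple[np.ndarray, bool]:
    sd = v.std()
    if sd < _VAR_EPS:
        return np.zeros_like(v), True
    return (v - v.mean()) / sd, False


# ---------------------------------------------------------------------------
# forward model


def gaussian_profile(prf: GaussianPRF, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Unit-peak Gaussian pRF profile on coordinate grids (beta excluded)."""
    d2 = (X - prf.x_deg) ** 2 + (Y - prf.y_deg) ** 2
    return np.exp(-d2 / (2.0 * prf.sigma_deg**2))


class _FitContext:
    """Cached per-movie quantities shared across many vertex fits."""

    def __init__(self, movie: ApertureMovie, hrf: TwoGammaHRF):
        movie = movie.analysis()
        self.movie = movie
        self.hrf = hrf
        X, Y = movie.grid()
        self.Xf = X.ravel()
        self.Yf = Y.ravel()
        self.frames = movie.frames.reshape(movie.n_frames, -1).astype(float)
        self.kernel = sample_kernel(hrf, movie.tr_s, KERNEL_DURATION_S)
        self.n_frames = movie.n_frames

    def overlap(self, x: float, y: float, sigma: float) -> np.ndarray:
        g = np.exp(-((self.Xf - x) ** 2 + (self.Yf - y) ** 2) / (2.0 * sigma**2))
        return self.frames @ g

    def conv_overlap(self, x: float, y: float, sigma: float) -> np.ndarray:
        o = self.overlap(x, y, sigma)
        if o.std() < 1e-9 * max(np.abs(o).max(), 1.0):
            return np.zeros(self.n_frames)  # constant drive: degenerate
        return np.convolve(o, self.kernel)[: self.n_frames]


def overlap_timecourse(prf: GaussianPRF, movie: ApertureMovie) -> np.ndarray:
    """Per-frame overlap between aperture and unit-peak Gaussian profile."""
    X, Y = movie.grid()
    g = gaussian_profile(prf, X, Y).ravel()
    return movie.frames.reshape(movie.n_frames, -1).astype(float) @ g


def predict_timeseries(
    prf: GaussianPRF,
    movie: ApertureMovie,
    hrf: TwoGammaHRF,
    standardize: bool = True,
) -> np.ndarray:
    """Predicted BOLD series: aperture-pRF overlap convolved with the HRF.

    With ``standardize=True`` the output is z-scored to match preprocessed
    data; a degenerate (constant) prediction returns all zeros, which
    callers treat as unfittable.  Movies are used as given: strip dummy
    frames with ``movie.analysis()`` first when predicting analysis data.
    """
    o = overlap_timecourse(prf, movie)
    if o.std() < _VAR_EPS:
        # constant stimulus drive (pRF outside the apertures, or stimulated
        # identically every frame): degenerate regardless of the HRF onset
        # transient the convolution would introduce
        return np.zeros(movie.n_frames)
    kern = sample_kernel(hrf, movie.tr_s, KERNEL_DURATION_S)
    c = np.convolve(o, kern)[: movie.n_frames]
    if not standardize:
        return c
    z, _ = _zscore(c)
    return z


def fitted_prediction(
    prf: GaussianPRF, movie: ApertureMovie, hrf: TwoGammaHRF
) -> np.ndarray:
    """Fine-stage model prediction on the z-scored data scale: beta times the
    mean-centered HRF-convolved overlap."""
    c = predict_timeseries(prf, movie, hrf, standardize=False)
    return prf.beta * (c - c.mean())


# ---------------------------------------------------------------------------
# coarse stage


def grid_predictions(
    movie: ApertureMovie, hrf: TwoGammaHRF, grid: SearchGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Z-scored predictions for every grid candidate: (N x T), plus a
    degeneracy mask for candidates with constant predictions."""
    ctx = _FitContext(movie, hrf)
    # (N, cells) Gaussian bank; fine at default grid sizes, chunk if large
    G = np.exp(
        -(
            (ctx.Xf[None, :] - grid.x[:, None]) ** 2
            + (ctx.Yf[None, :] - grid.y[:, None]) ** 2
        )
        / (2.0 * grid.sigma[:, None] ** 2)
    )
    O = G @ ctx.frames.T  # (N, T)
    C = signal.fftconvolve(O, ctx.kernel[None, :], axes=1)[:, : ctx.n_frames]
    # constant stimulus drive is degenerate even though the convolution's
    # onset transient leaves residual variance in C
    degenerate = (O.std(axis=1) < 1e-9 * np.maximum(np.abs(O).max(axis=1), 1.0)) \
        | (C.std(axis=1) < _VAR_EPS)
    sd_safe = np.where(degenerate, 1.0, C.std(axis=1))
    Z = (C - C.mean(axis=1, keepdims=True)) / sd_safe[:, None]
    Z[degenerate] = 0.0
    return Z, degenerate


def coarse_fit(
    smoothed_series: np.ndarray,
    movie: ApertureMovie,
    hrf: TwoGammaHRF,
    grid: SearchGrid,
    precomputed: tuple[np.ndarray, np.ndarray] | None = None,
) -> FitResult:
    """Grid search maximizing signed Pearson correlation (beta ignored).

    Ties break toward the lowest candidate index (enumeration order);
    degenerate candidate predictions score -inf.  An all-degenerate grid or
    a constant series yields an unfittable result.
    """
    z, bad = _zscore(np.asarray(smoothed_series, dtype=float))
    preds, degenerate = (
        precomputed if precomputed is not None else grid_predictions(movie, hrf, grid)
    )
    if bad or degenerate.all():
        return FitResult(
            prf=GaussianPRF(0.0, 0.0, grid.sigma[0], 0.0),
            r_squared=0.0, stage="coarse", correlation=None,
            converged=False, flags=("unfittable",),
        )
    corr = preds @ z / z.size
    corr[degenerate] = -np.inf
    best = int(np.argmax(corr))
    c = float(corr[best])
    return FitResult(
        prf=GaussianPRF(float(grid.x[best]), float(grid.y[best]),
                        float(grid.sigma[best]), 1.0),
        r_squared=min(max(c * c, 0.0), 1.0),
        stage="coarse",
        correlation=c,
    )


# ---------------------------------------------------------------------------
# fine stage


def fine_fit(
    series: np.ndarray,
    movie: ApertureMovie,
    hrf: TwoGammaHRF,
    init,
    max_ecc_deg: float | None = None,
    maxfev: int = 500,
    _ctx: "_FitContext | None" = None,
) -> FitResult:
    """Simplex refinement of (x, y, sigma) with beta profiled analytically.

    ``init`` is a coarse-stage :class:`FitResult` or a :class:`GaussianPRF`.
    r_squared is 1 - SS_res / SS_tot against the z-scored unsmoothed series.
    Non-convergence returns the best point found with ``converged=False``.
    """
    prf0 = init.prf if isinstance(init, FitResult) else init
    z, bad = _zscore(np.asarray(series, dtype=float))
    if bad:
        return FitResult(prf=prf0, r_squared=0.0, stage="fine",
                         converged=False, flags=("unfittable",))
    ctx = _ctx if _ctx is not None else _FitContext(movie, hrf)
    sst = float(z @ z)

    def beta_ssres(x: float, y: float, sigma: float) -> tuple[float, float]:
        c = ctx.conv_overlap(x, y, sigma)
        cc = c - c.mean()
        denom = float(cc @ cc)
        if denom < _VAR_EPS:
            return 0.0, sst
        beta = float(cc @ z) / denom
        return beta, sst - beta * beta * denom

    def loss(p):
        x, y, logs = p
        if max_ecc_deg is not None:
            ecc = math.hypot(x, y)
            if ecc > max_ecc_deg:
                return sst * (1.0 + ecc - max_ecc_deg)
        return beta_ssres(x, y, math.exp(logs))[1]

    x0 = np.array([prf0.x_deg, prf0.y_deg, math.log(prf0.sigma_deg)])
    # explicit initial simplex: the default one collapses for coordinates at 0
    # (pRFs on a meridian) and would pin them there
    d_pos = max(0.5, 0.5 * prf0.sigma_deg)
    simplex = np.tile(x0, (4, 1))
    simplex[1, 0] += d_pos
    simplex[2, 1] += d_pos
    simplex[3, 2] += 0.3
    res = optimize.minimize(
        loss, x0, method="Nelder-Mead",
        options=dict(xatol=1e-4, fatol=1e-8, maxfev=maxfev, maxiter=maxfev,
                     initial_simplex=simplex),
    )
    x, y, logs = res.x
    sigma = math.exp(logs)
    beta, ssres = beta_ssres(x, y, sigma)
    r2 = 1.0 - ssres / sst if sst > 0 else 0.0
    flags = []
    if beta < 0:
        flags.append("negative_beta")
    if abs(beta) == 0.0:
        flags.append("degenerate")
    return FitResult(
        prf=GaussianPRF(float(x), float(y), float(sigma), float(beta)),
        r_squared=min(max(r2, 0.0), 1.0),
        stage="fine",
        converged=bool(res.success),
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# smoothing + whole-surface driver


def smooth_temporal(data: np.ndarray, width: int = 3) -> np.ndarray:
    """Moving-average low-pass along time (stand-in for cortical smoothing
    when no vertex adjacency exists)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    kern = np.ones(width) / width
    pad = width // 2
    padded = np.pad(data, ((0, 0), (pad, pad)), mode="edge")
    out = np.apply_along_axis(lambda r: np.convolve(r, kern, mode="valid"), 1, padded)
    return out[:, : data.shape[1]]


def smooth_adjacency(data: np.ndarray, adjacency) -> np.ndarray:
    """Neighbor-graph averaging: each vertex averaged with its neighbors."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[0]
    out = np.empty_like(data)
    for i in range(n):
        nbrs = list(adjacency.get(i, [])) if hasattr(adjacency, "get") else list(adjacency[i])
        idx = [i] + [j for j in nbrs if 0 <= j < n]
        out[i] = data[idx].mean(axis=0)
    return out


def fit_surface(
    all_vertex_series: np.ndarray,
    movie: ApertureMovie,
    hrf: TwoGammaHRF,
    grid: SearchGrid | None = None,
    smoothing: str = "temporal",
    adjacency=None,
    maxfev: int = 500,
    n_starts: int = 3,
) -> list[FitResult]:
    """Coarse-to-fine fit for every vertex of a (vertices x volumes) matrix.

    The coarse stage runs on smoothed data (neighbor-graph averaging when an
    adjacency is supplied, else a width-3 temporal moving average), the fine
    stage on the unsmoothed series.  To guard against local minima of the
    fine objective the simplex search is restarted from the ``n_starts``
    best-correlated coarse candidates and the lowest-residual solution kept
    (``n_starts=1`` reproduces the plain coarse+fine composition).
    Deterministic given inputs.  Data with one extra dummy block matching
    the movie's dummy count are trimmed automatically.
    """
    data = np.atleast_2d(np.asarray(all_vertex_series, dtype=float))
    amovie = movie.analysis()
    if data.shape[1] == movie.n_frames and movie.n_dummy:
        data = data[:, movie.n_dummy:]
    if data.shape[1] != amovie.n_frames:
        raise ValueError(
            f"series length {data.shape[1]} does not match movie "
            f"analysis length {amovie.n_frames}"
        )
    if grid is None:
        grid = SearchGrid.default(movie.fov_radius_deg)
    if adjacency is not None:
        smoothed = smooth_adjacency(data, adjacency)
    elif smoothing == "temporal":
        smoothed = smooth_temporal(data)
    elif smoothing in (None, "none"):
        smoothed = data
    else:
        raise ValueError(f"unknown smoothing spec {smoothing!r}")

    preds, degenerate = grid_predictions(amovie, hrf, grid)
    ctx = _FitContext(amovie, hrf)
    results: list[FitResult] = []
    for v in range(data.shape[0]):
        coarse = coarse_fit(smoothed[v], amovie, hrf, grid,
                            precomputed=(preds, degenerate))
        if "unfittable" in coarse.flags:
            results.append(coarse)
            continue
        inits: list = [coarse]
        if n_starts > 1:
            # the characteristic local minimum is a sigma-collapsed pRF, and
            # a wide-sigma start reliably escapes it: always restart once
            # from the winning position with sigma inflated 4x
            wide_sigma = min(4.0 * coarse.prf.sigma_deg, float(grid.sigma.max()))
            inits.append(GaussianPRF(coarse.prf.x_deg, coarse.prf.y_deg,
                                     wide_sigma, 1.0))
            z, _ = _zscore(smoothed[v])
            corr = preds @ z / z.size
            corr[degenerate] = -np.inf
            chosen = [(coarse.prf.x_deg, coarse.prf.y_deg, coarse.prf.sigma_deg)]
            # restarts must sit in a different basin: far in position or at a
            # clearly different sigma scale
            min_sep = 0.1 * grid.max_ecc_deg
            for idx in np.argsort(corr)[::-1]:
                if len(inits) >= n_starts or not np.isfinite(corr[idx]):
                    break
                cand = (float(grid.x[idx]), float(grid.y[idx]), float(grid.sigma[idx]))
                distinct = all(
                    math.hypot(cand[0] - cx, cand[1] - cy) > min_sep
                    or abs(math.log(cand[2] / cs)) > math.log(2.0)
                    for cx, cy, cs in chosen
                )
                if distinct:
                    chosen.append(cand)
                    inits.append(GaussianPRF(*cand, 1.0))
        best: FitResult | None = None
        for init in inits:
            fine = fine_fit(data[v], amovie, hrf, init,
                            max_ecc_deg=grid.max_ecc_deg, maxfev=maxfev, _ctx=ctx)
            if best is None or fine.r_squared > best.r_squared:
                best = fine
        results.append(best)
    return results


def fits_to_frame(results, vertex_ids=None) -> pd.DataFrame:
    """Tabulate fit results: vertex id, x, y, sigma, beta, R^2, stage, flags."""
    if vertex_ids is None:
        vertex_ids = np.arange(len(results))
    rows = []
    for vid, r in zip(vertex_ids, results):
        rows.append(dict(
            vertex_id=vid,
            x=r.prf.x_deg, y=r.prf.y_deg, sigma=r.prf.sigma_deg, beta=r.prf.beta,
            r_squared=r.r_squared, stage=r.stage, converged=r.converged,
            flags=";".join(r.flags),
        ))
    return pd.DataFrame(rows)
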