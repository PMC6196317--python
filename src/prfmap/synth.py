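"""Synthetic retinotopic cortex: ground-truth pRF populations and noisy BOLD.

Generates vertex populations whose pRF centers tile the visual field
quadrant-by-quadrant the way early visual areas do (left-hemisphere areas
represent the right hemifield; dorsal areas the lower quadrant, ventral the
upper), with pRF size growing linearly with eccentricity and area-specific
slope multipliers (V1 < V2 < V3).  BOLD series are produced by the Gaussian
pRF forward model convolved with a two-gamma HRF plus iid Gaussian noise in
z units; optional "cortical scotoma" lesions silence the stimulus-driven
signal in a visual-field region while keeping the noise, so the pipeline's
ability to detect lost cortical function can be demonstrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .apertures import ApertureMovie
from .hrf import TwoGammaHRF, DEFAULT_HRF
from .prf import GaussianPRF, predict_timeseries

__all__ = [
    "SimulationSpec",
    "make_ground_truth",
    "simulate_timeseries",
    "recovery_report",
    "AREA_SIGMA_MULTIPLIERS",
    "truth_prfs",
]

# synthetic conventions for sigma growth per area (not empirical claims)
AREA_SIGMA_MULTIPLIERS = {"V1": 1.0, "V2": 1.5, "V3": 2.0}

_GROUPS = [
    # (hemisphere, area label, x sign, y sign): left hemisphere represents the
    # right hemifield; dorsal areas the lower quadrant, ventral the upper.
    ("left", "V1v", +1, +1), ("left", "V1d", +1, -1),
    ("left", "V2v", +1, +1), ("left", "V2d", +1, -1),
    ("left", "V3v", +1, +1), ("left", "V3d", +1, -1),
    ("right", "V1v", -1, +1), ("right", "V1d", -1, -1),
    ("right", "V2v", -1, +1), ("right", "V2d", -1, -1),
    ("right", "V3v", -1, +1), ("right", "V3d", -1, -1),
]


@dataclass
class SimulationSpec:
    """Conditions of one synthetic-cortex simulation.

    sigma(ecc) = sigma_intercept + sigma_slope * ecc (degrees), scaled by the
    area multiplier; noise_sd is in z units (data are z-standardized);
    lesion_predicate(x, y) -> True marks truth centers inside the simulated
    cortical scotoma.
    """

    n_vertices: int = 200
    fov_radius_deg: float = 37.5
    sigma_intercept: float = 0.5
    sigma_slope: float = 0.1
    noise_sd: float = 0.5
    seed: int = 0
    hemispheres: tuple[str, ...] = ("left", "right")
    areas: tuple[str, ...] = ("V1", "V2", "V3")
    lesion_predicate: Optional[Callable] = None
    ar1_rho: float = 0.0  # optional temporal autocorrelation, off by default

    def __post_init__(self) -> None:
        if self.n_vertices < 1:
            raise ValueError("need at least one vertex")
        if self.noise_sd < 0:
            raise ValueError("noise_sd cannot be negative")


def make_ground_truth(spec: SimulationSpec) -> pd.DataFrame:
    """Ground-truth vertex table: quasi-uniform pRF tiling per quadrant-area.

    Columns: vertex_id, hemisphere, area (V1v..V3d), x, y, sigma, beta,
    lesion.  Centers are drawn uniformly over each group's quadrant disk
    (area-uniform in eccentricity); a group with a single vertex sits at the
    quadrant center.  Deterministic given the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    groups = [g for g in _GROUPS
              if g[0] in spec.hemispheres and g[1][:2] in spec.areas]
    counts = np.full(len(groups), spec.n_vertices // len(groups), dtype=int)
    counts[: spec.n_vertices % len(groups)] += 1

    rows = []
    vid = 0
    fov = spec.fov_radius_deg
    for (hemi, area, xs, ys), count in zip(groups, counts):
        mult = AREA_SIGMA_MULTIPLIERS[area[:2]]
        for i in range(count):
            if count == 1:
                # single vertex: quadrant center (bisector angle, half FOV)
                r, a = fov / 2.0, np.pi / 4.0
            else:
                r = fov * np.sqrt(rng.uniform(0.0025, 1.0))
                a = rng.uniform(0.0, np.pi / 2.0)
            x = xs * r * np.cos(a)
            y = ys * r * np.sin(a)
            ecc = np.hypot(x, y)
            sigma = mult * (spec.sigma_intercept + spec.sigma_slope * ecc)
            lesion = bool(spec.lesion_predicate(x, y)) if spec.lesion_predicate else False
            rows.append(dict(vertex_id=vid, hemisphere=hemi, area=area,
                             x=float(x), y=float(y), sigma=float(sigma),
                             beta=1.0, lesion=lesion))
            vid += 1
    return pd.DataFrame(rows)


def truth_prfs(truth: pd.DataFrame) -> list[GaussianPRF]:
    """Ground-truth rows as GaussianPRF objects (in table order)."""
    return [GaussianPRF(r.x, r.y, r.sigma, r.beta)
            for r in truth.itertuples(index=False)]


def simulate_timeseries(
    truth: pd.DataFrame,
    movie: ApertureMovie,
    hrf: TwoGammaHRF = DEFAULT_HRF,
    noise_sd: float = 0.5,
    seed: int = 0,
    ar1_rho: float = 0.0,
) -> np.ndarray:
    """Noisy BOLD matrix (vertices x analysis volumes) from ground truth.

    Each vertex's signal is the z-scored forward-model prediction for its
    true pRF over the movie's analysis frames; lesioned vertices emit pure
    noise (signal silenced, noise variance kept).  Noise is iid Gaussian in
    z units, optionally AR(1)-correlated with coefficient ``ar1_rho``.
    Bit-identical output for a fixed (truth, movie, hrf, noise_sd, seed).
    """
    rng = np.random.default_rng(seed)
    amovie = movie.analysis()
    n_t = amovie.n_frames
    data = np.empty((len(truth), n_t), dtype=float)
    for i, row in enumerate(truth.itertuples(index=False)):
        if row.lesion:
            signal = np.zeros(n_t)
        else:
            prf = GaussianPRF(row.x, row.y, row.sigma, row.beta)
            signal = row.beta * predict_timeseries(prf, amovie, hrf)
        noise = rng.normal(0.0, noise_sd, size=n_t) if noise_sd > 0 else 0.0
        if ar1_rho and noise_sd > 0:
            noise = _ar1(noise, ar1_rho)
        data[i] = signal + noise
    return data


def _ar1(white: np.ndarray, rho: float) -> np.ndarray:
    out = np.empty_like(white)
    out[0] = white[0]
    for t in range(1, white.size):
        out[t] = rho * out[t - 1] + np.sqrt(1 - rho**2) * white[t]
    return out


def recovery_report(
    truth: pd.DataFrame,
    fits: pd.DataFrame,
    threshold: float = 0.05,
) -> dict:
    """Parameter-recovery and lesion-detection summary.

    Joins truth and fits on vertex_id; over non-lesioned vertices whose fit
    passes the R^2 threshold, reports per-parameter bias, RMSE and
    truth-fit Pearson correlation, plus the joint position RMSE
    sqrt(mean(dx^2 + dy^2)).  Lesion detection treats sub-threshold R^2 as
    "detected": sensitivity over lesioned vertices, specificity over intact
    ones.
    """
    merged = truth.merge(fits, on="vertex_id", suffixes=("_true", "_fit"))
    if merged.empty:
        raise ValueError("truth and fits share no vertex ids")
    intact = merged[~merged["lesion"]]
    good = intact[intact["r_squared"] >= threshold]
    report: dict = {"n_vertices": len(merged), "n_scored": len(good),
                    "threshold": threshold}
    for param in ("x", "y", "sigma", "beta"):
        t = good[f"{param}_true"].to_numpy()
        f = good[f"{param}_fit"].to_numpy()
        d = f - t
        entry = dict(bias=float(d.mean()) if d.size else np.nan,
                     rmse=float(np.sqrt((d**2).mean())) if d.size else np.nan)
        if d.size >= 2 and np.std(t) > 0 and np.std(f) > 0:
            entry["correlation"] = float(np.corrcoef(t, f)[0, 1])
        else:
            entry["correlation"] = np.nan
        report[param] = entry
    if len(good):
        dx = good["x_fit"].to_numpy() - good["x_true"].to_numpy()
        dy = good["y_fit"].to_numpy() - good["y_true"].to_numpy()
        report["position_rmse"] = float(np.sqrt((dx**2 + dy**2).mean()))
    else:
        report["position_rmse"] = np.nan
    lesioned = merged[merged["lesion"]]
    detected_lesion = (lesioned["r_squared"] < threshold).to_numpy()
    intact_pass = (intact["r_squared"] >= threshold).to_numpy()
    report["lesion_sensitivity"] = (
        float(detected_lesion.mean()) if len(lesioned) else np.nan
    )
    report["lesion_specificity"] = (
        float(intact_pass.mean()) if len(intact) else np.nan
    )
    return report
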