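"""Retinotopic map quantities, visual-field coverage, and eccentricity-band
summaries.

Fitted pRF centers are converted to polar angle (counter-clockwise from
3 o'clock, in [0, 360)) and eccentricity; maps expose an R^2-thresholded
view (default cutoff 0.05).  Visual-field coverage is the pointwise sum of
unit-peak Gaussian pRF profiles over a region of interest; per-band means
and SEMs of sigma, beta or R^2 against eccentricity reproduce the standard
summary plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .apertures import grid_centers
from .prf import GaussianPRF, gaussian_profile

__all__ = [
    "to_polar",
    "to_cartesian",
    "RetinotopicMap",
    "CoverageMap",
    "field_coverage",
    "bin_by_eccentricity",
    "sample_timeseries_figure",
]


def to_polar(x_deg, y_deg):
    """(x, y) -> (polar angle in [0, 360) CCW from 3 o'clock, eccentricity)."""
    x = np.asarray(x_deg, dtype=float)
    y = np.asarray(y_deg, dtype=float)
    angle = np.degrees(np.arctan2(y, x)) % 360.0
    # a denormal negative angle can round the modulo up to exactly 360
    angle = np.where(angle >= 360.0, 0.0, angle)
    ecc = np.hypot(x, y)
    if np.isscalar(x_deg) and np.isscalar(y_deg):
        return float(angle), float(ecc)
    return angle, ecc


def to_cartesian(polar_angle_deg, eccentricity_deg):
    """Inverse of :func:`to_polar`."""
    a = np.deg2rad(np.asarray(polar_angle_deg, dtype=float))
    e = np.asarray(eccentricity_deg, dtype=float)
    x, y = e * np.cos(a), e * np.sin(a)
    if np.isscalar(polar_angle_deg) and np.isscalar(eccentricity_deg):
        return float(x), float(y)
    return x, y


@dataclass
class RetinotopicMap:
    """Per-vertex retinotopic quantities with an R^2 threshold mask.

    ``table`` columns: vertex_id, polar_angle_deg, eccentricity_deg,
    sigma_deg, beta, r_squared, and optionally roi_label.
    """

    table: pd.DataFrame
    threshold: float = 0.05

    REQUIRED = ("vertex_id", "polar_angle_deg", "eccentricity_deg",
                "sigma_deg", "beta", "r_squared")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"map table missing columns: {missing}")
        if (self.table["eccentricity_deg"] < 0).any():
            raise ValueError("eccentricity cannot be negative")

    @classmethod
    def from_fits(
        cls,
        fits: pd.DataFrame,
        threshold: float = 0.05,
        roi: pd.DataFrame | None = None,
    ) -> "RetinotopicMap":
        """Build a map from a fits table (vertex_id, x, y, sigma, beta,
        r_squared); ``roi`` optionally joins per-vertex area labels."""
        angle, ecc = to_polar(fits["x"].to_numpy(), fits["y"].to_numpy())
        table = pd.DataFrame(dict(
            vertex_id=fits["vertex_id"].to_numpy(),
            polar_angle_deg=np.atleast_1d(angle),
            eccentricity_deg=np.atleast_1d(ecc),
            sigma_deg=fits["sigma"].to_numpy(),
            beta=fits["beta"].to_numpy(),
            r_squared=fits["r_squared"].to_numpy(),
        ))
        if roi is not None:
            table = table.merge(roi[["vertex_id", "roi_label"]],
                                on="vertex_id", how="left")
        return cls(table=table, threshold=threshold)

    @property
    def thresholded(self) -> pd.DataFrame:
        """Vertices whose model fit explains at least ``threshold`` variance."""
        return self.table[self.table["r_squared"] >= self.threshold]

    def with_threshold(self, threshold: float) -> "RetinotopicMap":
        return RetinotopicMap(table=self.table, threshold=threshold)


@dataclass
class CoverageMap:
    """Summed pRF profiles over a visual-field grid (non-negative)."""

    values: np.ndarray
    fov_radius_deg: float
    area: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < -1e-12).any():
            raise ValueError("coverage cannot be negative")

    @property
    def grid_n(self) -> int:
        return self.values.shape[0]

    def grid(self):
        return grid_centers(self.grid_n, self.fov_radius_deg)

    def value_at(self, x_deg: float, y_deg: float) -> float:
        """Coverage at the grid cell nearest the requested location."""
        c = np.linspace(-self.fov_radius_deg, self.fov_radius_deg, self.grid_n)
        j = int(np.argmin(np.abs(c - x_deg)))
        i = int(np.argmin(np.abs(c - y_deg)))
        return float(self.values[i, j])


def field_coverage(
    prfs,
    fov_radius_deg: float,
    grid_n: int = 101,
    beta_weighted: bool = False,
    normalize: bool = False,
    area: str | None = None,
) -> CoverageMap:
    """Visual-field coverage: the sum of all pRFs' unit-peak Gaussian profiles.

    Unweighted by default (each pRF contributes a unit-peak Gaussian);
    ``beta_weighted`` scales each profile by its amplitude, ``normalize``
    divides by the pRF count.  An empty pRF set yields an all-zero map with a
    warning.
    """
    prfs = list(prfs)
    X, Y = grid_centers(grid_n, fov_radius_deg)
    values = np.zeros((grid_n, grid_n), dtype=float)
    if not prfs:
        warnings.warn("empty pRF set: coverage map is all zero", stacklevel=2)
        return CoverageMap(values=values, fov_radius_deg=fov_radius_deg, area=area)
    for prf in prfs:
        w = prf.beta if beta_weighted else 1.0
        values += w * gaussian_profile(prf, X, Y)
    if normalize:
        values /= len(prfs)
    return CoverageMap(values=values, fov_radius_deg=fov_radius_deg, area=area)


def bin_by_eccentricity(
    map_or_table,
    quantity: str,
    band_edges=None,
    stimulus_ecc_deg: float | None = None,
    n_bands: int = 9,
) -> pd.DataFrame:
    """Mean and SEM of a map quantity in half-open eccentricity bands.

    ``quantity`` is a column of the (thresholded) map table, e.g.
    'sigma_deg', 'beta' or 'r_squared'.  Bands default to ``n_bands``
    equal-width bands from 0 to the stimulus outer eccentricity.  Empty
    bands report NaN means (missing, not zero); single-vertex bands report
    NaN SEM.
    """
    if isinstance(map_or_table, RetinotopicMap):
        table = map_or_table.thresholded
    else:
        table = map_or_table
    if band_edges is None:
        if stimulus_ecc_deg is None:
            raise ValueError("supply band_edges or stimulus_ecc_deg")
        band_edges = np.linspace(0.0, stimulus_ecc_deg, n_bands + 1)
    band_edges = np.asarray(band_edges, dtype=float)
    if (np.diff(band_edges) <= 0).any():
        raise ValueError("band edges must be strictly increasing")
    ecc = table["eccentricity_deg"].to_numpy()
    vals = table[quantity].to_numpy()
    rows = []
    for lo, hi in zip(band_edges[:-1], band_edges[1:]):
        sel = (ecc >= lo) & (ecc < hi)
        n = int(sel.sum())
        if n == 0:
            mean = sem = np.nan
        else:
            mean = float(vals[sel].mean())
            sem = float(vals[sel].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append(dict(band_lo=lo, band_hi=hi, n=n, mean=mean, sem=sem))
    return pd.DataFrame(rows)


def sample_timeseries_figure(
    fits: pd.DataFrame,
    series: np.ndarray,
    predictions: np.ndarray,
    vertex_ids,
) -> pd.DataFrame:
    """Aligned observed/predicted traces for example vertices (long format).

    ``series`` and ``predictions`` are (vertices x volumes) matrices indexed
    like the fits table rows; output columns are vertex_id, volume,
    observed, predicted.  Unknown vertex ids raise a lookup error.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    predictions = np.atleast_2d(np.asarray(predictions, dtype=float))
    index = {vid: i for i, vid in enumerate(fits["vertex_id"].to_numpy())}
    rows = []
    for vid in vertex_ids:
        if vid not in index:
            raise KeyError(f"unknown vertex id {vid!r}")
        i = index[vid]
        for t, (obs, pred) in enumerate(zip(series[i], predictions[i])):
            rows.append(dict(vertex_id=vid, volume=t,
                             observed=float(obs), predicted=float(pred)))
    return pd.DataFrame(rows, columns=["vertex_id", "volume", "observed", "predicted"])
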