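"""Binary stimulus-aperture movies for retinotopic mapping.

An aperture movie is the stimulus model for pRF fitting: one binary mask of
stimulated visual-field locations per acquisition volume, on a square grid of
cell centers spanning [-fov, +fov] degrees in both axes.  Three run types are
supported: rotating wedges (polar angle), expanding/contracting rings
(eccentricity), and full-field on/off trials (HRF estimation).  A region mask
(e.g. keep only the upper-right quadrant) builds the scotoma-masked control
stimulus model.

Conventions: x rightward, y upward, fixation at the origin; polar angle 0 deg
at 3 o'clock increasing counter-clockwise.  The grid is odd-sized by default
(101 x 101) so one cell center sits exactly at fixation.  Central fixation
region and contrast ramps are treated as stimulated; a binary aperture cannot
represent ramped contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ApertureMovie",
    "RunDesign",
    "DesignError",
    "ResolutionError",
    "SESSION_PRESETS",
    "make_wedge_movie",
    "make_ring_movie",
    "make_fullfield_movie",
    "make_session_run",
    "finalize_run",
    "mask_region",
    "run_duration_s",
    "quadrant_predicate",
    "grid_centers",
]

_EPS = 1e-9


class DesignError(ValueError):
    """A run design violates the stimulus geometry constraints."""


class ResolutionError(ValueError):
    """The aperture grid is too coarse to represent the stimulus."""


def grid_centers(grid_n: int, fov_radius_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Cell-center coordinate grids (X, Y), each ``grid_n x grid_n``.

    Row index increases with y so that ``frames[t, i, j]`` is the cell at
    ``(X[i, j], Y[i, j])``; visualization tools may flip as needed.
    """
    c = np.linspace(-fov_radius_deg, fov_radius_deg, grid_n)
    X, Y = np.meshgrid(c, c, indexing="xy")
    return X, Y


def _in_field(grid_n: int, fov_radius_deg: float) -> np.ndarray:
    X, Y = grid_centers(grid_n, fov_radius_deg)
    return X * X + Y * Y <= fov_radius_deg**2 + _EPS


@dataclass
class ApertureMovie:
    """Per-volume binary visual-field masks plus acquisition metadata.

    frames : (T, grid_n, grid_n) array of 0/1
    fov_radius_deg : visual-field radius represented by the grid edge
    tr_s : repetition time in seconds
    labels : per-frame tag (wedge | ring | blank | dummy | fullfield)
    """

    frames: np.ndarray
    fov_radius_deg: float
    tr_s: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.uint8)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.frames.shape[2]:
            raise ValueError("frames must be (T, grid_n, grid_n)")
        if not np.isin(self.frames, (0, 1)).all():
            raise ValueError("frames must be binary")
        if len(self.labels) != self.n_frames:
            raise ValueError("labels must have one entry per frame")
        if self.tr_s <= 0 or self.fov_radius_deg <= 0:
            raise ValueError("tr_s and fov_radius_deg must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_n(self) -> int:
        return self.frames.shape[1]

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        return grid_centers(self.grid_n, self.fov_radius_deg)

    def analysis(self) -> "ApertureMovie":
        """Drop dummy frames (discarded volumes) for analysis-side use."""
        keep = [i for i, lab in enumerate(self.labels) if lab != "dummy"]
        return replace(
            self,
            frames=self.frames[keep],
            labels=[self.labels[i] for i in keep],
        )

    @property
    def n_dummy(self) -> int:
        return sum(1 for lab in self.labels if lab == "dummy")

    def concat(self, other: "ApertureMovie") -> "ApertureMovie":
        if other.grid_n != self.grid_n or other.fov_radius_deg != self.fov_radius_deg:
            raise ValueError("cannot concatenate movies with different grids")
        if other.tr_s != self.tr_s:
            raise ValueError("cannot concatenate movies with different TR")
        return replace(
            self,
            frames=np.concatenate([self.frames, other.frames]),
            labels=self.labels + other.labels,
        )


@dataclass
class RunDesign:
    """Declarative description of one mapping run segment."""

    kind: str  # wedge | ring | fullfield
    n_cycles: int = 1
    n_steps: int = 1
    blank_volumes: int = 0
    dummy_volumes: int = 3
    direction: str = "clockwise"

    def __post_init__(self) -> None:
        if self.n_cycles <= 0 or self.n_steps <= 0:
            raise DesignError("cycle/step counts must be strictly positive")
        if self.blank_volumes < 0 or self.dummy_volumes < 0:
            raise DesignError("blank/dummy volume counts cannot be negative")


def _validate_grid(grid_n: int) -> None:
    if grid_n < 16:
        raise ResolutionError(f"grid_n={grid_n} too coarse (minimum 16)")


def make_wedge_movie(
    width_deg: float = 36.0,
    step_deg: float = 18.0,
    n_cycles: int = 8,
    fov_radius_deg: float = 37.5,
    grid_n: int = 101,
    tr_s: float = 3.0,
    direction: str = "clockwise",
    start_angle_deg: float = 90.0,
) -> ApertureMovie:
    """Rotating-wedge movie: one rotation step per acquisition volume.

    Frame k's wedge spans polar angles [a_k, a_k + width_deg) with
    a_k = start_angle_deg -/+ k * step_deg for clockwise/anticlockwise
    rotation.  Each cycle has 360/step_deg frames; the default design (36 deg
    wedge stepping 18 deg at TR 3 s) completes a cycle in 60 s.
    """
    _validate_grid(grid_n)
    if not (0 < width_deg <= 360):
        raise DesignError("width_deg must be in (0, 360]")
    if step_deg <= 0 or abs(360 / step_deg - round(360 / step_deg)) > 1e-9:
        raise DesignError("360 must be an integer multiple of step_deg")
    if direction not in ("clockwise", "anticlockwise"):
        raise DesignError(f"unknown wedge direction {direction!r}")
    frames_per_cycle = int(round(360 / step_deg))
    sign = -1.0 if direction == "clockwise" else 1.0

    X, Y = grid_centers(grid_n, fov_radius_deg)
    theta = np.degrees(np.arctan2(Y, X)) % 360.0
    infield = _in_field(grid_n, fov_radius_deg)

    cycle = np.empty((frames_per_cycle, grid_n, grid_n), dtype=np.uint8)
    for k in range(frames_per_cycle):
        a = (start_angle_deg + sign * k * step_deg) % 360.0
        wedge = ((theta - a) % 360.0) < width_deg - _EPS
        cycle[k] = (wedge & infield).astype(np.uint8)
    frames = np.tile(cycle, (n_cycles, 1, 1))
    return ApertureMovie(
        frames=frames,
        fov_radius_deg=fov_radius_deg,
        tr_s=tr_s,
        labels=["wedge"] * (frames_per_cycle * n_cycles),
    )


def make_ring_movie(
    n_steps: int = 16,
    n_reps: int = 10,
    fov_radius_deg: float = 37.5,
    inner_radius_deg: float = 0.28,
    grid_n: int = 101,
    tr_s: float = 3.0,
    direction: str = "expanding",
) -> ApertureMovie:
    """Expanding/contracting ring movie with log-spaced radii.

    Ring mid-radii are logarithmically spaced between inner_radius_deg and
    fov_radius_deg (constant ratio between consecutive steps); ring i covers
    the annulus between the geometric midpoints to its neighbors so the
    sequence tiles eccentricity without gaps.  One frame per step, the whole
    cycle repeated n_reps times; "contracting" reverses within-cycle order.
    """
    _validate_grid(grid_n)
    if n_steps < 2:
        raise DesignError("n_steps must be >= 2")
    if inner_radius_deg <= 0:
        raise DesignError("inner_radius_deg must be positive")
    if inner_radius_deg >= fov_radius_deg:
        raise DesignError("inner_radius_deg must be smaller than fov_radius_deg")
    if direction not in ("expanding", "contracting"):
        raise DesignError(f"unknown ring direction {direction!r}")

    mid = np.geomspace(inner_radius_deg, fov_radius_deg, n_steps)
    half = (fov_radius_deg / inner_radius_deg) ** (0.5 / (n_steps - 1))
    X, Y = grid_centers(grid_n, fov_radius_deg)
    R = np.hypot(X, Y)
    infield = _in_field(grid_n, fov_radius_deg)

    cycle = np.empty((n_steps, grid_n, grid_n), dtype=np.uint8)
    for i, r in enumerate(mid):
        ring = (R >= r / half) & (R < r * half)
        cycle[i] = (ring & infield).astype(np.uint8)
    if direction == "contracting":
        cycle = cycle[::-1]
    frames = np.tile(cycle, (n_reps, 1, 1))
    return ApertureMovie(
        frames=frames,
        fov_radius_deg=fov_radius_deg,
        tr_s=tr_s,
        labels=["ring"] * (n_steps * n_reps),
    )


def make_fullfield_movie(
    n_trials: int = 10,
    on_volumes: int = 1,
    off_volumes: int = 9,
    fov_radius_deg: float = 37.5,
    grid_n: int = 101,
    tr_s: float = 3.0,
) -> ApertureMovie:
    """Full-field on/off movie for HRF estimation.

    Each trial shows the full stimulated disk for ``on_volumes`` volumes then
    a blank for ``off_volumes`` volumes (default 1 volume = 3 s on, 27 s off,
    10 trials).
    """
    _validate_grid(grid_n)
    if n_trials <= 0 or on_volumes <= 0 or off_volumes < 0:
        raise DesignError("trial/volume counts must be positive")
    disk = _in_field(grid_n, fov_radius_deg).astype(np.uint8)
    blank = np.zeros_like(disk)
    trial = np.stack([disk] * on_volumes + [blank] * off_volumes)
    frames = np.tile(trial, (n_trials, 1, 1))
    labels = (["fullfield"] * on_volumes + ["blank"] * off_volumes) * n_trials
    return ApertureMovie(
        frames=frames, fov_radius_deg=fov_radius_deg, tr_s=tr_s, labels=labels
    )


def finalize_run(
    movie: ApertureMovie, blank_volumes: int, dummy_volumes: int = 3
) -> ApertureMovie:
    """Prepend dummy (discarded) volumes and append end-of-run blanks."""
    if movie.n_frames == 0:
        raise DesignError("cannot finalize an empty movie")
    blank = np.zeros((1, movie.grid_n, movie.grid_n), dtype=np.uint8)
    parts = [np.tile(blank, (dummy_volumes, 1, 1)), movie.frames,
             np.tile(blank, (blank_volumes, 1, 1))]
    labels = (["dummy"] * dummy_volumes) + movie.labels + (["blank"] * blank_volumes)
    return replace(movie, frames=np.concatenate(parts), labels=labels)


def mask_region(
    movie: ApertureMovie,
    region_predicate: Callable[[np.ndarray, np.ndarray], np.ndarray],
) -> ApertureMovie:
    """Multiply every frame by a keep-mask derived from a visual-field predicate.

    ``region_predicate(x, y)`` receives coordinate arrays in degrees and
    returns True where the stimulus should be *kept*.  Used to build the
    scotoma-masked control stimulus model (e.g. keep only the upper-right
    quadrant).  A predicate removing every in-field cell yields a fully blank
    model: degenerate but legal, so it warns rather than raises.
    """
    X, Y = movie.grid()
    keep = np.asarray(region_predicate(X, Y))
    if keep.shape != X.shape:  # scalar predicate; vectorize as a fallback
        keep = np.vectorize(region_predicate)(X, Y)
    keep = keep.astype(bool)
    if not (keep & _in_field(movie.grid_n, movie.fov_radius_deg)).any():
        warnings.warn("mask removes every in-field cell: stimulus model is blank",
                      stacklevel=2)
    return replace(movie, frames=(movie.frames * keep.astype(np.uint8)))


def quadrant_predicate(name: str) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Keep-predicate for one visual-field quadrant ('upper-right', ...)."""
    preds = {
        "upper-right": lambda x, y: (x > 0) & (y > 0),
        "upper-left": lambda x, y: (x < 0) & (y > 0),
        "lower-left": lambda x, y: (x < 0) & (y < 0),
        "lower-right": lambda x, y: (x > 0) & (y < 0),
    }
    try:
        return preds[name]
    except KeyError:
        raise ValueError(f"unknown quadrant {name!r}; choose from {sorted(preds)}")


def run_duration_s(movie: ApertureMovie) -> float:
    """Total run duration: frame count x TR."""
    return movie.n_frames * movie.tr_s


# Printed design parameters of the two scanning sessions: session 1 used a
# wide-field (37.5 deg radius) projection, session 2 a narrow field (9 deg).
SESSION_PRESETS: dict[int, dict] = {
    1: dict(
        fov_radius_deg=37.5,
        tr_s=3.0,
        wedge=dict(width_deg=36.0, step_deg=18.0, n_cycles=8),
        ring=dict(n_steps=16, n_reps=10),
        fullfield=dict(n_trials=10, on_volumes=1, off_volumes=9),
        blank_volumes=20,
        dummy_volumes=3,
    ),
    2: dict(
        fov_radius_deg=9.0,
        tr_s=3.0,
        wedge=dict(width_deg=36.0, step_deg=18.0, n_cycles=3),
        ring=dict(n_steps=12, n_reps=5),
        fullfield=dict(n_trials=10, on_volumes=1, off_volumes=9),
        blank_volumes=15,
        dummy_volumes=3,
    ),
}


def make_session_run(
    session: int,
    kind: str,
    grid_n: int = 101,
    direction: str | None = None,
    finalized: bool = True,
    **overrides,
) -> ApertureMovie:
    """Build one preset run ('wedge' | 'ring' | 'fullfield') for a session.

    Session presets encode the printed scan designs; any design parameter can
    be overridden by keyword.  ``finalized`` adds the dummy and end-of-run
    blank volumes (full-field runs get dummies but no trailing blank block).
    """
    if session not in SESSION_PRESETS:
        raise DesignError(f"unknown session {session}; choose 1 or 2")
    preset = SESSION_PRESETS[session]
    common = dict(fov_radius_deg=preset["fov_radius_deg"], tr_s=preset["tr_s"],
                  grid_n=grid_n)
    if kind == "wedge":
        kwargs = {**preset["wedge"], **common}
        if direction is not None:
            kwargs["direction"] = direction
        kwargs.update(overrides)
        movie = make_wedge_movie(**kwargs)
        blank = preset["blank_volumes"]
    elif kind == "ring":
        kwargs = {**preset["ring"], **common}
        if direction is not None:
            kwargs["direction"] = direction
        kwargs.update(overrides)
        movie = make_ring_movie(**kwargs)
        blank = preset["blank_volumes"]
    elif kind == "fullfield":
        kwargs = {**preset["fullfield"], **common}
        kwargs.update(overrides)
        movie = make_fullfield_movie(**kwargs)
        blank = 0
    else:
        raise DesignError(f"unknown run kind {kind!r}")
    if finalized:
        movie = finalize_run(movie, blank_volumes=blank,
                             dummy_volumes=preset["dummy_volumes"])
    return movie
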