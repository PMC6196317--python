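"""Readers/writers and the end-to-end pipeline driver.

Formats: NIfTI for aperture movies (grid_n x grid_n x 1 x volumes, binary)
and vertex time series (vertices x 1 x 1 x volumes), each with a JSON
sidecar carrying fov_radius_deg / tr_s / labels; TSV with a header line for
fits, truth and summary tables (vertex_id is the join key); JSON manifests
recording seeds and parameters; YAML pipeline configs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .apertures import ApertureMovie, make_session_run, mask_region, quadrant_predicate
from .hrf import DEFAULT_HRF, TwoGammaHRF, estimate_hrf
from .maps import RetinotopicMap, bin_by_eccentricity, field_coverage
from .prf import SearchGrid, fit_surface, fits_to_frame
from .synth import SimulationSpec, make_ground_truth, recovery_report, simulate_timeseries, truth_prfs

log = logging.getLogger("prfmap")

__all__ = [
    "save_movie", "load_movie",
    "save_timeseries", "load_timeseries",
    "save_table", "load_table",
    "save_hrf", "load_hrf",
    "run_pipeline",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def save_movie(movie: ApertureMovie, path) -> Path:
    """Write an aperture movie as NIfTI plus a JSON sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(
        movie.frames.transpose(1, 2, 0)[:, :, None, :].astype(np.uint8), np.eye(4)
    )
    img.header.set_zooms((1.0, 1.0, 1.0, movie.tr_s))
    nib.save(img, str(path))
    sidecar = dict(fov_radius_deg=movie.fov_radius_deg, tr_s=movie.tr_s,
                   labels=movie.labels)
    _sidecar_path(path).write_text(json.dumps(sidecar))
    return path


def load_movie(path) -> ApertureMovie:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    frames = data[:, :, 0, :].transpose(2, 0, 1)
    meta = json.loads(_sidecar_path(path).read_text())
    return ApertureMovie(frames=frames, fov_radius_deg=meta["fov_radius_deg"],
                         tr_s=meta["tr_s"], labels=list(meta["labels"]))


def save_timeseries(data: np.ndarray, path, tr_s: float | None = None,
                    vertex_ids=None) -> Path:
    """Write a vertices x volumes matrix as NIfTI (.nii/.nii.gz) or TSV."""
    path = Path(path)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if path.suffix in (".nii", ".gz"):
        img = nib.Nifti1Image(data[:, None, None, :], np.eye(4))
        if tr_s:
            img.header.set_zooms((1.0, 1.0, 1.0, tr_s))
        nib.save(img, str(path))
        if tr_s is not None:
            _sidecar_path(path).write_text(json.dumps(dict(tr_s=tr_s)))
    else:
        df = pd.DataFrame(data)
        df.insert(0, "vertex_id",
                  vertex_ids if vertex_ids is not None else np.arange(len(df)))
        df.to_csv(path, sep="\t", index=False)
    return path


def load_timeseries(path, movie: ApertureMovie | None = None,
                    drop_dummies: bool = True) -> tuple[np.ndarray, dict]:
    """Load a vertices x volumes matrix from NIfTI or TSV.

    With a reference ``movie``, the volume count is validated against the
    movie, the TR sidecar (if any) is checked against the movie's TR (a
    mismatch is a hard error), and the movie's dummy volumes are dropped
    from the front when ``drop_dummies``.  All-NaN rows are flagged
    unfittable in the returned metadata rather than raised.
    """
    path = Path(path)
    meta: dict = {}
    if path.suffix in (".nii", ".gz"):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError("expected a 4-D NIfTI time series")
        data = data.reshape(-1, data.shape[-1])
        sc = _sidecar_path(path)
        if sc.exists():
            meta.update(json.loads(sc.read_text()))
    else:
        df = pd.read_csv(path, sep="\t")
        if df.empty:
            raise ValueError(f"{path} holds no time series")
        if "vertex_id" in df.columns:
            meta["vertex_ids"] = df["vertex_id"].to_numpy()
            df = df.drop(columns=["vertex_id"])
        data = df.to_numpy(dtype=float)
    if movie is not None:
        if "tr_s" in meta and not np.isclose(meta["tr_s"], movie.tr_s):
            raise ValueError(
                f"TR mismatch: series {meta['tr_s']} s vs movie {movie.tr_s} s"
            )
        if data.shape[1] == movie.n_frames and drop_dummies and movie.n_dummy:
            data = data[:, movie.n_dummy:]
        elif data.shape[1] != movie.analysis().n_frames:
            raise ValueError(
                f"series has {data.shape[1]} volumes; movie expects "
                f"{movie.n_frames} (or {movie.analysis().n_frames} after dummies)"
            )
    meta["unfittable"] = np.isnan(data).all(axis=1)
    data = np.nan_to_num(data)
    return data, meta


def save_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")


def save_hrf(hrf: TwoGammaHRF, path, residual_norm: float | None = None) -> Path:
    path = Path(path)
    rec = dict(amplitude=hrf.amplitude, peak_latency_s=hrf.peak_latency_s,
               undershoot_latency_s=hrf.undershoot_latency_s, ratio=hrf.ratio)
    if residual_norm is not None:
        rec["residual_norm"] = residual_norm
    path.write_text(json.dumps(rec, indent=1))
    return path


def load_hrf(path) -> TwoGammaHRF:
    rec = json.loads(Path(path).read_text())
    return TwoGammaHRF(rec["amplitude"], rec["peak_latency_s"],
                       rec["undershoot_latency_s"], rec["ratio"])


# ---------------------------------------------------------------------------
# pipeline driver


DEFAULT_CONFIG = dict(
    session=1,
    grid_n=61,
    n_vertices=100,
    noise_sd=0.5,
    seed=0,
    threshold=0.05,
    mask_keep=None,       # e.g. "upper-right" for the control stimulus model
    lesion_quadrants=None,  # e.g. ["lower-left"] to simulate a scotoma
)


def run_pipeline(config: dict | str | Path, out_dir) -> dict:
    """Synthetic end-to-end run: apertures -> simulate -> HRF -> pRF -> maps.

    ``config`` is a dict or a YAML file with :data:`DEFAULT_CONFIG` keys.
    Writes movies, truth/fits tables, the fitted HRF, band summaries, a
    coverage grid and a manifest (seed, versions, parameters) into
    ``out_dir``; reruns with the same config are bit-identical.  Returns the
    recovery report.
    """
    if not isinstance(config, dict):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    session, grid_n, seed = cfg["session"], cfg["grid_n"], cfg["seed"]
    log.info("stage=apertures session=%s grid_n=%s", session, grid_n)
    wedge = make_session_run(session, "wedge", grid_n=grid_n)
    ring = make_session_run(session, "ring", grid_n=grid_n)
    ff = make_session_run(session, "fullfield", grid_n=grid_n)
    mapping = wedge.concat(ring)
    save_movie(mapping, out / "mapping.nii")
    save_movie(ff, out / "fullfield.nii")

    fov = mapping.fov_radius_deg
    lesion_pred = None
    if cfg["lesion_quadrants"]:
        quads = [quadrant_predicate(q) for q in cfg["lesion_quadrants"]]
        lesion_pred = lambda x, y: any(bool(np.asarray(q(x, y))) for q in quads)
    spec = SimulationSpec(n_vertices=cfg["n_vertices"], fov_radius_deg=fov,
                          noise_sd=cfg["noise_sd"], seed=seed,
                          lesion_predicate=lesion_pred)
    truth = make_ground_truth(spec)
    save_table(truth, out / "truth.tsv")

    log.info("stage=simulate n_vertices=%s noise_sd=%s", len(truth), cfg["noise_sd"])
    hrf_data = simulate_timeseries(truth, ff, DEFAULT_HRF,
                                   noise_sd=cfg["noise_sd"], seed=seed + 1)
    data = simulate_timeseries(truth, mapping, DEFAULT_HRF,
                               noise_sd=cfg["noise_sd"], seed=seed + 2)
    save_timeseries(data, out / "series.tsv")

    log.info("stage=fit-hrf")
    trial_len = 10
    onsets = list(range(0, ff.analysis().n_frames, trial_len))
    hrf, resid = estimate_hrf(hrf_data, onsets, trial_len, ff.tr_s)
    save_hrf(hrf, out / "hrf.json", residual_norm=resid)

    fit_movie = mapping
    if cfg["mask_keep"]:
        fit_movie = mask_region(mapping, quadrant_predicate(cfg["mask_keep"]))
    log.info("stage=fit-prf masked=%s", bool(cfg["mask_keep"]))
    grid = SearchGrid.default(fov)
    fits = fits_to_frame(fit_surface(data, fit_movie, hrf, grid),
                         vertex_ids=truth["vertex_id"].to_numpy())
    save_table(fits, out / "fits.tsv")

    log.info("stage=maps threshold=%s", cfg["threshold"])
    rmap = RetinotopicMap.from_fits(fits, threshold=cfg["threshold"])
    save_table(rmap.table, out / "map.tsv")
    for qty in ("sigma_deg", "beta", "r_squared"):
        save_table(bin_by_eccentricity(rmap, qty, stimulus_ecc_deg=fov),
                   out / f"bands_{qty}.tsv")
    good = fits[fits["r_squared"] >= cfg["threshold"]]
    cov = field_coverage(truth_prfs(good), fov_radius_deg=fov, grid_n=grid_n)
    np.savetxt(out / "coverage.tsv", cov.values, delimiter="\t")

    report = recovery_report(truth, fits, threshold=cfg["threshold"])
    manifest = dict(config=cfg, version=__version__, seed=seed,
                    n_volumes=int(data.shape[1]), report=report)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=float))
    log.info("stage=report position_rmse=%.3f", report["position_rmse"])
    return report
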