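"""End-to-end orchestration: stream -> localizations -> events -> lifetimes
-> target classification -> rendered images and metrics.

:class:`PipelineConfig` carries every stage parameter with the defaults of
the reference analysis: 8x spatial binning / 500 ms time bins for
wide-field, 8-frame time bins for confocal, PSF-width rejection at 345 nm
(wide-field) or 180 nm (confocal), a 100-photon minimum, the single-frame
discard rule, a 0.1 ns tail offset for the lifetime fit and the
0.5-5.0 ns accepted lifetime range.  Any override is logged.  A fixed seed
makes a rerun bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fltime, localize, multiplex, photonio, postproc
from .errors import InvalidConfigurationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All analysis parameters; defaults follow the reference protocol."""

    mode: str = "widefield"  # 'widefield' | 'confocal'
    n_targets: int = 2
    # binning
    spatial_bin: int = 8
    time_bin_s: float = 0.5
    frames_per_bin: int = 8
    # detection / fitting
    detection_threshold: float = 5.0
    roi_half: int = 3
    template_sigma_nm: float = 150.0
    # filtering
    max_sigma_nm: float | None = None  # auto: 345 widefield / 180 confocal
    min_photons: int = 100
    # linking
    max_displacement_px: float = 2.0  # in virtual pixels
    max_gap_frames: int = 1
    # lifetime
    tail_offset_ns: float = 0.1
    tau_min_ns: float = 0.5
    tau_max_ns: float = 5.0
    min_tail_photons: int = 50
    collect_radius_px: float = 2.0
    background_mixture: bool = True  # uniform-background term in the tail fit
    # drift
    drift_correction: bool = True
    drift_segments: int = 10
    # rendering
    render_pixel_nm: float = 20.0
    # bookkeeping
    seed: int = 0
    output_dir: str = "flpaint_out"

    def __post_init__(self) -> None:
        if self.mode not in ("widefield", "confocal"):
            raise InvalidConfigurationError(f"mode must be widefield or confocal, got {self.mode!r}")
        if self.n_targets < 1:
            raise InvalidConfigurationError("n_targets must be >= 1")
        if self.tau_min_ns >= self.tau_max_ns:
            raise InvalidConfigurationError("need tau_min_ns < tau_max_ns")

    @property
    def sigma_limit_nm(self) -> float:
        if self.max_sigma_nm is not None:
            return self.max_sigma_nm
        return localize.MAX_SIGMA_NM[self.mode]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidConfigurationError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        defaults = cls()
        for fld in dataclasses.fields(cls):
            if getattr(cfg, fld.name) != getattr(defaults, fld.name):
                logger.info("config override: %s = %r", fld.name, getattr(cfg, fld.name))
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def event_micro_times(events, stream) -> list[np.ndarray]:
    """Per-event photon delays gathered through the photon-id links."""
    return [stream.micro_time[ev.photon_ids] for ev in events]


def analyze_stream(
    stream: photonio.PhotonStream, config: PipelineConfig
) -> dict:
    """Run the analysis stages on one photon stream.

    Returns a dict with the localization table, linked events, the event
    table (positions, lifetimes, assignments), the lifetime mixture,
    thresholds, crosstalk matrix and rendered images.
    """
    # --- binning
    if config.mode == "widefield":
        stack = localize.bin_widefield(stream, config.spatial_bin, config.time_bin_s)
    else:
        stack = localize.bin_confocal(stream, config.frames_per_bin)
    vpx = stack.virtual_pixel_size

    # --- detection + fitting + filtering
    locs = localize.localize_frames(
        stack,
        template_sigma_px=config.template_sigma_nm / vpx,
        detection_threshold=config.detection_threshold,
        roi_half=config.roi_half,
        collect_radius_px=config.collect_radius_px,
    )
    locs = localize.filter_localizations(locs, config.sigma_limit_nm, config.min_photons)

    # --- linking
    events = localize.link_events(
        locs, config.max_displacement_px * vpx, config.max_gap_frames
    )

    # --- per-event lifetimes
    micro = event_micro_times(events, stream)
    collect_area_px2 = (2.0 * config.collect_radius_px) ** 2
    fits = []
    for ev, t in zip(events, micro):
        f_bg = 0.0
        if config.background_mixture and len(t):
            # expected uniform-background admixture from the fitted per-pixel
            # background of the member localizations
            bg_expected = float(
                locs["background"].iloc[ev.loc_indices].sum() * collect_area_px2
            )
            f_bg = min(bg_expected / len(t), 0.5)
        fits.append(
            fltime.fit_lifetime_tail(
                t,
                tail_offset=config.tail_offset_ns,
                window_end=stream.tcspc_window,
                min_photons=config.min_tail_photons,
                background_fraction=f_bg,
            )
        )
    ev_rows = []
    for ev, fit in zip(events, fits):
        first = int(locs["frame"].iloc[ev.loc_indices].min())
        ev_rows.append(
            {
                "event_id": ev.event_id,
                "frame": first,
                "x_nm": ev.mean_x,
                "y_nm": ev.mean_y,
                "z_nm": 0.0,
                "photons": ev.total_photons,
                "background": float(locs["background"].iloc[ev.loc_indices].mean()),
                "sigma_nm": float(locs["sigma_nm"].iloc[ev.loc_indices].mean()),
                "precision_nm": float(locs["precision_nm"].iloc[ev.loc_indices].mean())
                / np.sqrt(len(ev.loc_indices)),
                "tau_ns": fit.tau,
                "tau_err_ns": fit.tau_stderr,
                "duration_frames": ev.duration_frames,
                "target_id": -1,
            }
        )
    ev_table = pd.DataFrame(
        ev_rows,
        columns=[
            "event_id", "frame", "x_nm", "y_nm", "z_nm", "photons", "background",
            "sigma_nm", "precision_nm", "tau_ns", "tau_err_ns", "duration_frames", "target_id",
        ],
    )
    ev_table = fltime.filter_lifetimes(ev_table, config.tau_min_ns, config.tau_max_ns)
    kept_ids = set(ev_table["event_id"].tolist())
    events = [ev for ev in events if ev.event_id in kept_ids]

    # --- drift correction on event positions
    trajectory = None
    if config.drift_correction and len(ev_table) >= 300:
        times = ev_table["frame"].to_numpy(float) * stack.bin_duration
        seg = max(times.max() / config.drift_segments, stack.bin_duration)
        try:
            trajectory = postproc.estimate_drift(ev_table, times, seg)
            ev_table = postproc.apply_drift(ev_table, times, trajectory)
        except ValueError as exc:
            logger.warning("drift correction skipped: %s", exc)

    # --- classification
    mixture = thresholds = crosstalk = None
    classification = None
    if len(ev_table) >= 50 * config.n_targets:
        mixture = multiplex.fit_lifetime_mixture(
            ev_table["tau_ns"].to_numpy(float),
            config.n_targets,
            fit_range=(config.tau_min_ns, config.tau_max_ns),
        )
        thresholds = multiplex.derive_thresholds(mixture)
        classification = multiplex.classify_by_threshold(
            ev_table["tau_ns"].to_numpy(float), thresholds, mixture
        )
        crosstalk = multiplex.estimate_crosstalk(mixture, thresholds)
        ev_table = ev_table.copy()
        ev_table["target_id"] = classification.target_id
        for k in range(config.n_targets):
            ev_table[f"posterior_p{k + 1}"] = classification.posteriors[:, k]
    else:
        logger.warning("too few events (%d) for a %d-component mixture", len(ev_table), config.n_targets)

    # --- rendering
    images = None
    if len(ev_table):
        images = postproc.split_targets(
            ev_table,
            ev_table["target_id"].to_numpy()
            if "target_id" in ev_table
            else np.full(len(ev_table), -1),
            config.render_pixel_nm,
            colormap_limits=(config.tau_min_ns, config.tau_max_ns),
        )

    return {
        "frame_stack": stack,
        "localizations": locs,
        "events": events,
        "event_table": ev_table,
        "mixture": mixture,
        "thresholds": thresholds,
        "crosstalk": crosstalk,
        "classification": classification,
        "drift": trajectory,
        "images": images,
    }


def run_pipeline(config: PipelineConfig, stream_path: str | Path) -> dict:
    """Run the full analysis on a stream container and write all artifacts.

    Writes localization and event CSVs, per-target and overlay images, a
    metrics JSON and a provenance record into ``config.output_dir``.
    """
    from . import __version__

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stream = photonio.read_photon_stream(stream_path)
    result = analyze_stream(stream, config)

    loc_export = result["localizations"].drop(columns=["photon_ids"], errors="ignore").copy()
    loc_export.insert(0, "event_id", -1)
    for ev in result["events"]:
        loc_export.loc[loc_export.index.isin(ev.loc_indices), "event_id"] = ev.event_id
    for col, val in (("z_nm", 0.0), ("tau_ns", np.nan), ("tau_err_ns", np.nan), ("target_id", -1)):
        loc_export[col] = val
    photonio.write_localizations(loc_export, out / "localizations.csv")
    photonio.write_localizations(result["event_table"], out / "events.csv")

    metrics: dict = {"n_localizations": len(result["localizations"]), "n_events": len(result["event_table"])}
    if result["images"] is not None:
        photonio.export_image(result["images"]["overlay"], out / "overlay_intensity.tif", "intensity")
        photonio.export_image(result["images"]["overlay"], out / "overlay_lifetime.tif", "lifetime")
        for k, img in result["images"]["targets"].items():
            photonio.export_image(img, out / f"target_{k}_intensity.tif", "intensity")
    if result["mixture"] is not None:
        metrics["mixture"] = {
            "weights": result["mixture"].weights.tolist(),
            "means_ns": result["mixture"].means.tolist(),
            "sigmas_ns": result["mixture"].sigmas.tolist(),
        }
        metrics["thresholds_ns"] = result["thresholds"].tolist()
        metrics["crosstalk"] = result["crosstalk"].tolist()
        np.savetxt(out / "crosstalk.csv", result["crosstalk"], delimiter=",", fmt="%.6g")
    ev_tab = result["event_table"]
    if len(ev_tab):
        metrics["mean_precision_nm"] = float(ev_tab["precision_nm"].mean())
        metrics["mean_photons_per_event"] = float(ev_tab["photons"].mean())
    metrics["provenance"] = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "package_version": __version__,
        "input": str(stream_path),
    }
    with open(out / "metrics.json", "w") as f:
        json.dump(metrics, f, indent=2)
    result["metrics"] = metrics
    return result


# ---------------------------------------------------------------------------
# truth matching (simulation validation)


def match_events_to_truth(
    ev_table: pd.DataFrame,
    truth: pd.DataFrame,
    bin_duration: float,
    max_distance_nm: float = 300.0,
) -> np.ndarray:
    """Match recovered events to ground-truth events by time overlap and
    proximity; returns the truth row index per event (-1 if unmatched)."""
    out = np.full(len(ev_table), -1, dtype=int)
    t_start = truth["start_s"].to_numpy(float)
    t_end = t_start + truth["duration_s"].to_numpy(float)
    tx = truth["x_nm"].to_numpy(float)
    ty = truth["y_nm"].to_numpy(float)
    for i, row in enumerate(ev_table.itertuples()):
        ev_t0 = row.frame * bin_duration
        ev_t1 = ev_t0 + max(getattr(row, "duration_frames", 1), 1) * bin_duration
        overlap = (t_start < ev_t1) & (t_end > ev_t0)
        if not overlap.any():
            continue
        cand = np.flatnonzero(overlap)
        d = np.hypot(tx[cand] - row.x_nm, ty[cand] - row.y_nm)
        j = int(np.argmin(d))
        if d[j] <= max_distance_nm:
            out[i] = cand[j]
    return out
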