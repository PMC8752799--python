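"""Drift correction, super-resolution rendering and quality metrics.

Drift is estimated by redundant cross-correlation (RCC): the movie is cut
into time segments, a histogram image is rendered per segment, shifts are
measured between *all* segment pairs by phase cross-correlation, and the
over-determined pairwise system is solved by least squares for one offset
per segment (anchored at zero for the first).  The recovered trajectory is
interpolated linearly in time and subtracted from the localizations —
applying a known trajectory and then correcting with it restores the input
exactly.

Rendering accumulates localizations on a fine pixel grid either as plain
2-D counts or as unit-mass Gaussians with the per-localization precision;
a parallel channel holds the intensity-weighted mean lifetime per pixel
for the lifetime-coloured images.

Image quality is quantified by the mean CRLB localization precision, a
nearest-neighbour (NeNA) precision estimate from repeated localizations of
the same binding event, and Fourier ring correlation (FRC) resolution at
the 1/7 threshold, including a per-block resolution map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FRC_THRESHOLD = 1.0 / 7.0


# ---------------------------------------------------------------------------
# drift


@dataclass
class DriftTrajectory:
    """Piecewise-linear stage drift, anchored at (0, 0) for the first segment."""

    times: np.ndarray  # s, segment centres
    dx: np.ndarray  # nm
    dy: np.ndarray  # nm
    interpolation: str = "linear"

    def at(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Drift at time ``t``: linear interpolation between segment centres,
        linear extrapolation beyond the first/last centre."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = []
        for comp in (self.dx, self.dy):
            v = np.interp(t, self.times, comp)
            if len(self.times) >= 2:
                slope_lo = (comp[1] - comp[0]) / (self.times[1] - self.times[0])
                slope_hi = (comp[-1] - comp[-2]) / (self.times[-1] - self.times[-2])
                lo = t < self.times[0]
                hi = t > self.times[-1]
                v = np.where(lo, comp[0] + slope_lo * (t - self.times[0]), v)
                v = np.where(hi, comp[-1] + slope_hi * (t - self.times[-1]), v)
            out.append(v)
        return out[0], out[1]


def _render_hist(x, y, extent, pixel) -> np.ndarray:
    nx = max(1, int(np.ceil((extent[1] - extent[0]) / pixel)))
    ny = max(1, int(np.ceil((extent[3] - extent[2]) / pixel)))
    h, _, _ = np.histogram2d(
        y, x, bins=(ny, nx), range=((extent[2], extent[2] + ny * pixel), (extent[0], extent[0] + nx * pixel))
    )
    return h


def estimate_drift(
    locs: pd.DataFrame,
    times: np.ndarray,
    segment_duration: float,
    render_pixel_nm: float = 30.0,
    min_locs_per_segment: int = 100,
) -> DriftTrajectory:
    """Redundant cross-correlation drift estimate.

    ``times`` gives the acquisition time (s) of each localization.  Segments
    with fewer than ``min_locs_per_segment`` localizations are merged with
    their successor.
    """
    from scipy.ndimage import gaussian_filter
    from skimage.registration import phase_cross_correlation

    x = locs["x_nm"].to_numpy(float)
    y = locs["y_nm"].to_numpy(float)
    times = np.asarray(times, dtype=float)
    t_end = times.max() + 1e-9
    edges = list(np.arange(0.0, t_end, segment_duration)) + [t_end]
    # merge under-filled segments forward
    merged_edges = [edges[0]]
    count_since = 0
    for lo, hi in zip(edges[:-1], edges[1:]):
        count_since += int(np.sum((times >= lo) & (times < hi)))
        if count_since >= min_locs_per_segment or hi == edges[-1]:
            merged_edges.append(hi)
            count_since = 0
    if len(merged_edges) < 3:
        raise ValueError("too few populated segments for drift estimation")
    if len(merged_edges) - 1 < len(edges) - 1:
        logger.info(
            "estimate_drift: merged %d under-filled segments", (len(edges) - len(merged_edges))
        )
    edges = np.asarray(merged_edges)
    n_seg = len(edges) - 1
    extent = (x.min(), x.max() + render_pixel_nm, y.min(), y.max() + render_pixel_nm)
    images = []
    centres = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (times >= lo) & (times < hi)
        # light smoothing stabilizes the correlation peak on sparse images
        images.append(gaussian_filter(_render_hist(x[m], y[m], extent, render_pixel_nm), 1.0))
        centres.append(0.5 * (lo + hi))
    # pairwise shifts, solved redundantly; plain (unnormalized) correlation —
    # spectral whitening amplifies shot noise on sparse reconstructions
    rows, shifts_x, shifts_y = [], [], []
    for i in range(n_seg):
        for j in range(i + 1, n_seg):
            shift, _, _ = phase_cross_correlation(
                images[i], images[j], upsample_factor=50, normalization=None
            )
            # shift = displacement of image j relative to i in (row, col)
            row = np.zeros(n_seg)
            row[i], row[j] = -1.0, 1.0
            rows.append(row)
            shifts_y.append(-shift[0] * render_pixel_nm)
            shifts_x.append(-shift[1] * render_pixel_nm)
    A = np.vstack(rows)[:, 1:]  # anchor segment 0 at zero drift
    dx = np.concatenate([[0.0], np.linalg.lstsq(A, np.asarray(shifts_x), rcond=None)[0]])
    dy = np.concatenate([[0.0], np.linalg.lstsq(A, np.asarray(shifts_y), rcond=None)[0]])
    return DriftTrajectory(times=np.asarray(centres), dx=dx, dy=dy)


def apply_drift(locs: pd.DataFrame, times: np.ndarray, trajectory: DriftTrajectory, subtract: bool = True) -> pd.DataFrame:
    """Subtract (or add, ``subtract=False``) the drift trajectory from positions."""
    dx, dy = trajectory.at(times)
    sign = -1.0 if subtract else 1.0
    out = locs.copy()
    out["x_nm"] = out["x_nm"].to_numpy(float) + sign * dx
    out["y_nm"] = out["y_nm"].to_numpy(float) + sign * dy
    return out


# ---------------------------------------------------------------------------
# rendering


@dataclass
class RenderedImage:
    """Intensity plus mean-lifetime channels on a fine pixel grid."""

    intensity: np.ndarray  # (ny, nx)
    lifetime: np.ndarray  # (ny, nx), NaN where intensity == 0
    render_pixel_size: float  # nm
    origin_nm: tuple[float, float] = (0.0, 0.0)
    colormap_limits: tuple[float, float] = (0.5, 5.0)  # ns


def render(
    locs: pd.DataFrame,
    render_pixel_size: float,
    mode: str = "histogram",
    extent_nm: tuple[float, float, float, float] | None = None,
    colormap_limits: tuple[float, float] = (0.5, 5.0),
) -> RenderedImage:
    """Reconstruct a super-resolution image from localizations.

    ``histogram`` mode bins positions into 2-D counts; ``gaussian`` mode
    spreads each localization as a unit-mass Gaussian of its precision.
    The lifetime channel is the intensity-weighted mean ``tau_ns`` per
    pixel (NaN where empty).
    """
    x = locs["x_nm"].to_numpy(float) if len(locs) else np.empty(0)
    y = locs["y_nm"].to_numpy(float) if len(locs) else np.empty(0)
    tau = (
        locs["tau_ns"].to_numpy(float)
        if "tau_ns" in getattr(locs, "columns", [])
        else np.full(len(x), np.nan)
    )
    if extent_nm is None:
        if len(x) == 0:
            extent_nm = (0.0, render_pixel_size, 0.0, render_pixel_size)
        else:
            extent_nm = (x.min(), x.max() + render_pixel_size, y.min(), y.max() + render_pixel_size)
    x0, x1, y0, y1 = extent_nm
    nx = max(1, int(np.ceil((x1 - x0) / render_pixel_size)))
    ny = max(1, int(np.ceil((y1 - y0) / render_pixel_size)))
    intensity = np.zeros((ny, nx))
    tau_sum = np.zeros((ny, nx))

    if mode == "histogram":
        ix = np.floor((x - x0) / render_pixel_size).astype(np.int64)
        iy = np.floor((y - y0) / render_pixel_size).astype(np.int64)
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        np.add.at(intensity, (iy[inside], ix[inside]), 1.0)
        t = np.nan_to_num(tau[inside], nan=0.0)
        np.add.at(tau_sum, (iy[inside], ix[inside]), t)
    elif mode == "gaussian":
        prec = (
            locs["precision_nm"].to_numpy(float)
            if "precision_nm" in locs.columns
            else np.full(len(x), render_pixel_size)
        )
        for xi, yi, pi, ti in zip(x, y, prec, tau):
            s = max(pi, 0.25 * render_pixel_size) / render_pixel_size
            cx = (xi - x0) / render_pixel_size
            cy = (yi - y0) / render_pixel_size
            r = int(np.ceil(4 * s)) + 1
            jx0, jx1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r
            jy0, jy1 = int(np.floor(cy)) - r, int(np.floor(cy)) + r
            jx0, jx1 = max(jx0, 0), min(jx1, nx - 1)
            jy0, jy1 = max(jy0, 0), min(jy1, ny - 1)
            if jx1 < jx0 or jy1 < jy0:
                continue
            from scipy.special import erf

            gx = np.arange(jx0, jx1 + 1)
            gy = np.arange(jy0, jy1 + 1)
            s2 = s * np.sqrt(2.0)
            wx = 0.5 * (erf((gx + 1 - cx) / s2) - erf((gx - cx) / s2))
            wy = 0.5 * (erf((gy + 1 - cy) / s2) - erf((gy - cy) / s2))
            patch = np.outer(wy, wx)
            intensity[jy0 : jy1 + 1, jx0 : jx1 + 1] += patch
            if np.isfinite(ti):
                tau_sum[jy0 : jy1 + 1, jx0 : jx1 + 1] += patch * ti
    else:
        raise ValueError(f"unknown render mode {mode!r}")

    lifetime = np.full_like(intensity, np.nan)
    nzero = intensity > 0
    lifetime[nzero] = tau_sum[nzero] / intensity[nzero]
    return RenderedImage(
        intensity=intensity,
        lifetime=lifetime,
        render_pixel_size=render_pixel_size,
        origin_nm=(x0, y0),
        colormap_limits=colormap_limits,
    )


def split_targets(
    locs: pd.DataFrame,
    target_id: np.ndarray,
    render_pixel_size: float,
    mode: str = "histogram",
    **render_kw,
) -> dict:
    """Render one image per assigned target plus the combined overlay.

    Returns ``{'targets': {k: RenderedImage}, 'overlay': RenderedImage}``;
    unassigned events (-1) appear only in the overlay.
    """
    target_id = np.asarray(target_id)
    x = locs["x_nm"].to_numpy(float)
    y = locs["y_nm"].to_numpy(float)
    ext = render_kw.pop(
        "extent_nm",
        (x.min(), x.max() + render_pixel_size, y.min(), y.max() + render_pixel_size)
        if len(x)
        else None,
    )
    images = {}
    for k in sorted(set(target_id[target_id >= 0].tolist())):
        images[int(k)] = render(
            locs.loc[target_id == k], render_pixel_size, mode, extent_nm=ext, **render_kw
        )
    overlay = render(locs, render_pixel_size, mode, extent_nm=ext, **render_kw)
    return {"targets": images, "overlay": overlay}


def assemble_zstack(
    per_plane_locs: dict[int, pd.DataFrame],
    render_pixel_size: float,
    z_step_nm: float = 500.0,
    mode: str = "histogram",
) -> dict:
    """Stack per-plane reconstructions and build a height-coloured z-projection.

    Returns ``{'volume': (nz, ny, nx), 'projection_rgb': (ny, nx, 3),
    'z_values_nm': array}``; hue encodes height, value encodes intensity.
    """
    from matplotlib.colors import hsv_to_rgb

    planes = sorted(per_plane_locs)
    xs = np.concatenate([per_plane_locs[p]["x_nm"].to_numpy(float) for p in planes])
    ys = np.concatenate([per_plane_locs[p]["y_nm"].to_numpy(float) for p in planes])
    ext = (xs.min(), xs.max() + render_pixel_size, ys.min(), ys.max() + render_pixel_size)
    renders = [render(per_plane_locs[p], render_pixel_size, mode, extent_nm=ext) for p in planes]
    volume = np.stack([r.intensity for r in renders])
    z_values = np.asarray(planes, dtype=float) * z_step_nm
    total = volume.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_z = np.where(total > 0, (volume * z_values[:, None, None]).sum(axis=0) / total, 0.0)
    span = max(z_values.max() - z_values.min(), 1.0)
    hue = (mean_z - z_values.min()) / span * (2.0 / 3.0)
    value = total / total.max() if total.max() > 0 else total
    rgb = hsv_to_rgb(np.stack([hue, np.ones_like(hue), value], axis=-1))
    return {"volume": volume, "projection_rgb": rgb, "z_values_nm": z_values}


# ---------------------------------------------------------------------------
# precision metrics


def summarize_precision(
    locs: pd.DataFrame, event_of_loc: np.ndarray | None = None
) -> dict:
    """Mean CRLB precision and NeNA estimate.

    NeNA uses the displacement between consecutive-frame localizations of
    the same binding event: for two independent localizations of one
    emitter, each with isotropic precision sigma, the distance is Rayleigh
    with scale ``sigma * sqrt(2)``, so ``sigma_NeNA = sqrt(mean(d^2) / 4)``.
    Returns NaN (flagged) when no repeated localizations exist.
    """
    out = {
        "mean_crlb_precision_nm": float(locs["precision_nm"].mean())
        if len(locs) and "precision_nm" in locs.columns
        else np.nan
    }
    d2 = []
    if event_of_loc is not None and len(locs):
        frames = locs["frame"].to_numpy()
        x = locs["x_nm"].to_numpy(float)
        y = locs["y_nm"].to_numpy(float)
        ev = np.asarray(event_of_loc)
        for e in np.unique(ev[ev >= 0]):
            idx = np.flatnonzero(ev == e)
            idx = idx[np.argsort(frames[idx])]
            for a, b in zip(idx[:-1], idx[1:]):
                if frames[b] - frames[a] == 1:
                    d2.append((x[b] - x[a]) ** 2 + (y[b] - y[a]) ** 2)
    out["nena_precision_nm"] = float(np.sqrt(np.mean(d2) / 4.0)) if d2 else np.nan
    out["nena_n_pairs"] = len(d2)
    return out


# ---------------------------------------------------------------------------
# Fourier ring correlation


def frc_curve(img1: np.ndarray, img2: np.ndarray, pixel_nm: float):
    """FRC of two half-data reconstructions.

    Returns ``(spatial_freq_per_nm, frc_values)``.  Images are apodized
    with a Hann window to suppress edge artefacts.
    """
    ny, nx = img1.shape
    win = np.outer(np.hanning(ny), np.hanning(nx))
    # remove the mean first: the window envelope would otherwise correlate
    # even independent images at the lowest rings
    F1 = np.fft.fftshift(np.fft.fft2((img1 - img1.mean()) * win))
    F2 = np.fft.fftshift(np.fft.fft2((img2 - img2.mean()) * win))
    cy, cx = ny // 2, nx // 2
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(yy - cy, xx - cx).astype(np.int64)
    n_rings = min(cx, cy)
    num = np.bincount(r.ravel(), weights=np.real(F1 * np.conj(F2)).ravel(), minlength=n_rings)
    d1 = np.bincount(r.ravel(), weights=np.abs(F1).ravel() ** 2, minlength=n_rings)
    d2 = np.bincount(r.ravel(), weights=np.abs(F2).ravel() ** 2, minlength=n_rings)
    rings = np.arange(1, n_rings)
    denom = np.sqrt(d1[rings] * d2[rings])
    frc = np.where(denom > 0, num[rings] / np.maximum(denom, 1e-300), 0.0)
    freq = rings / (min(nx, ny) * pixel_nm)
    return freq, frc


def _frc_resolution_from_curve(freq: np.ndarray, frc: np.ndarray) -> float:
    """Resolution (nm) at the first sustained crossing below the 1/7 line.

    The curve is smoothed over three rings first; uncorrelated half-images
    fluctuate about zero from the lowest ring on and report as unresolved
    (NaN) instead of a spurious crossing.
    """
    if len(frc) >= 3:
        frc = np.convolve(frc, np.ones(3) / 3.0, mode="same")
    below = frc < FRC_THRESHOLD
    idx = np.flatnonzero(below)
    if len(idx) == 0:
        return np.nan  # never crosses: unresolved at the sampling
    i = idx[0]
    if i == 0:
        return np.nan
    # linear interpolation of the crossing
    f0, f1 = freq[i - 1], freq[i]
    c0, c1 = frc[i - 1], frc[i]
    fc = f0 + (FRC_THRESHOLD - c0) * (f1 - f0) / (c1 - c0)
    return float(1.0 / fc)


@dataclass
class ResolutionReport:
    mean_precision_nm: float
    nena_precision_nm: float
    frc_resolution_nm: float
    frc_freq: np.ndarray
    frc_values: np.ndarray
    resolution_map: np.ndarray | None = None
    map_mean_nm: float = np.nan
    map_min_nm: float = np.nan


def frc_resolution(
    locs: pd.DataFrame,
    event_of_loc: np.ndarray | None = None,
    render_pixel_nm: float = 10.0,
    n_blocks: int = 0,
    block_px: int = 64,
    min_locs_per_block: int = 2000,
    seed: int = 0,
) -> ResolutionReport:
    """FRC resolution from an event-wise random half split.

    Splitting by binding event (not individual localization) keeps the
    correlated repeats of one event on the same side, which would otherwise
    inflate the apparent resolution.  With ``n_blocks > 0`` a per-block
    resolution map over ``block_px`` render-pixel tiles is added (blocks
    with fewer than ``min_locs_per_block`` localizations are undefined).
    """
    rng = np.random.default_rng(seed)
    if len(locs) < 1e4:
        logger.warning("frc_resolution: < 1e4 localizations; FRC estimate will be noisy")
    if event_of_loc is None:
        half = rng.integers(0, 2, size=len(locs)).astype(bool)
    else:
        ev = np.asarray(event_of_loc)
        uniq = np.unique(ev)
        pick = rng.integers(0, 2, size=len(uniq)).astype(bool)
        half = pick[np.searchsorted(uniq, ev)]
    x = locs["x_nm"].to_numpy(float)
    y = locs["y_nm"].to_numpy(float)
    extent = (x.min(), x.max() + render_pixel_nm, y.min(), y.max() + render_pixel_nm)
    img1 = _render_hist(x[half], y[half], extent, render_pixel_nm)
    img2 = _render_hist(x[~half], y[~half], extent, render_pixel_nm)
    freq, frc = frc_curve(img1, img2, render_pixel_nm)
    res = _frc_resolution_from_curve(freq, frc)

    res_map = None
    map_mean = map_min = np.nan
    if n_blocks:
        ny, nx = img1.shape
        nbx = max(1, nx // block_px)
        nby = max(1, ny // block_px)
        res_map = np.full((nby, nbx), np.nan)
        for by in range(nby):
            for bx in range(nbx):
                sl = (slice(by * block_px, (by + 1) * block_px), slice(bx * block_px, (bx + 1) * block_px))
                b1, b2 = img1[sl], img2[sl]
                if b1.sum() + b2.sum() < min_locs_per_block:
                    continue
                f, c = frc_curve(b1, b2, render_pixel_nm)
                res_map[by, bx] = _frc_resolution_from_curve(f, c)
        finite = res_map[np.isfinite(res_map)]
        if len(finite):
            map_mean = float(finite.mean())
            map_min = float(finite.min())

    prec = summarize_precision(locs, event_of_loc)
    return ResolutionReport(
        mean_precision_nm=prec["mean_crlb_precision_nm"],
        nena_precision_nm=prec["nena_precision_nm"],
        frc_resolution_nm=res,
        frc_freq=freq,
        frc_values=frc,
        resolution_map=res_map,
        map_mean_nm=map_mean,
        map_min_nm=map_min,
    )
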