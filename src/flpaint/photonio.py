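"""Photon-stream data model and file I/O.

Two acquisition geometries are supported:

* **Wide-field** (:class:`CameraGeometry`) — an event-mode lifetime camera
  that tags every detected photon with a detector pixel coordinate, an
  absolute (macro) arrival time and a TCSPC delay (micro time).
* **Confocal** (:class:`ScanGeometry`) — a laser-scanning microscope whose
  photons additionally carry the scan address (frame index, implied
  line/pixel via the coordinate) and optionally a focal-plane index for
  z-stacks.

Conventions
-----------
* Pixel indices are 0-based.  Physical positions are in nanometres with the
  origin at the lower-left pixel corner; the centre of pixel ``i`` sits at
  ``(i + 0.5) * pixel_size``.
* ``micro_time`` is in nanoseconds and lies in ``[0, tcspc_window)``.
* ``macro_time`` is in seconds and must be non-decreasing.  Unsorted input
  is rejected rather than silently sorted, so that upstream bugs surface.

Streams are persisted in a single HDF5 container with an explicit schema
version; localization tables are plain CSV with a fixed, documented column
set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, InvalidConfigurationError, SchemaError

SCHEMA_VERSION = 1

#: Mandatory columns of a localization table, in canonical order.
LOCALIZATION_COLUMNS = [
    "event_id",
    "frame",
    "x_nm",
    "y_nm",
    "z_nm",
    "photons",
    "background",
    "sigma_nm",
    "precision_nm",
    "tau_ns",
    "tau_err_ns",
    "target_id",
]


@dataclass(frozen=True)
class CameraGeometry:
    """Wide-field event camera: sensor partition and sample-plane scale."""

    sensor_pixels: tuple[int, int] = (512, 512)
    raw_pixel_size_at_sample: float = 24.0  # nm
    spatial_binning: int = 8

    def __post_init__(self) -> None:
        if min(self.sensor_pixels) <= 0 or self.raw_pixel_size_at_sample <= 0:
            raise InvalidConfigurationError("sensor size and pixel size must be positive")
        if self.spatial_binning < 1:
            raise InvalidConfigurationError("spatial_binning must be >= 1")

    @property
    def field_of_view_nm(self) -> tuple[float, float]:
        return (
            self.sensor_pixels[0] * self.raw_pixel_size_at_sample,
            self.sensor_pixels[1] * self.raw_pixel_size_at_sample,
        )


@dataclass(frozen=True)
class ScanGeometry:
    """Confocal raster: region, virtual pixel size, dwell time, frame count."""

    region_um: tuple[float, float] = (20.0, 20.0)
    pixel_size_nm: float = 100.0
    dwell_time_us: float = 2.5
    frames_total: int = 1
    z_step_nm: float | None = None

    def __post_init__(self) -> None:
        if self.dwell_time_us <= 0 or self.pixel_size_nm <= 0:
            raise InvalidConfigurationError("dwell time and pixel size must be positive")
        if min(self.region_um) <= 0 or self.frames_total < 1:
            raise InvalidConfigurationError("scan region and frame count must be positive")

    @property
    def pixels(self) -> tuple[int, int]:
        """Raster dimensions (nx, ny); region must tile into whole pixels."""
        nx = round(self.region_um[0] * 1000.0 / self.pixel_size_nm)
        ny = round(self.region_um[1] * 1000.0 / self.pixel_size_nm)
        return nx, ny

    @property
    def frame_duration_s(self) -> float:
        nx, ny = self.pixels
        return nx * ny * self.dwell_time_us * 1e-6


@dataclass
class PhotonStream:
    """Ordered photon events plus the geometry needed to interpret them.

    ``x``/``y`` are native pixel coordinates (detector pixels for
    wide-field, scan pixels for confocal); ``frame_index`` and ``z_plane``
    are present for confocal streams and ``None`` for wide-field.
    """

    x: np.ndarray
    y: np.ndarray
    macro_time: np.ndarray  # s
    micro_time: np.ndarray  # ns
    geometry: CameraGeometry | ScanGeometry
    tcspc_resolution: float  # ns
    tcspc_window: float  # ns
    frame_index: np.ndarray | None = None
    z_plane: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.macro_time)
        for name in ("x", "y", "micro_time"):
            if len(getattr(self, name)) != n:
                raise InvalidConfigurationError(f"field {name!r} length mismatch")
        if self.tcspc_resolution <= 0 or self.tcspc_resolution >= self.tcspc_window:
            raise InvalidConfigurationError("need 0 < tcspc_resolution < tcspc_window")
        if n:
            if np.any(np.diff(self.macro_time) < 0):
                raise FormatError("photon stream is not sorted by macro_time")
            if self.micro_time.min() < 0 or self.micro_time.max() >= self.tcspc_window:
                raise InvalidConfigurationError(
                    "micro_time outside [0, tcspc_window)"
                )

    def __len__(self) -> int:
        return len(self.macro_time)

    @property
    def pixel_size_nm(self) -> float:
        if isinstance(self.geometry, CameraGeometry):
            return self.geometry.raw_pixel_size_at_sample
        return self.geometry.pixel_size_nm

    def equals(self, other: "PhotonStream") -> bool:
        def _eq(a, b):
            if a is None or b is None:
                return (a is None) == (b is None)
            return np.array_equal(a, b)

        return (
            _eq(self.x, other.x)
            and _eq(self.y, other.y)
            and _eq(self.macro_time, other.macro_time)
            and _eq(self.micro_time, other.micro_time)
            and _eq(self.frame_index, other.frame_index)
            and _eq(self.z_plane, other.z_plane)
            and self.geometry == other.geometry
            and self.tcspc_resolution == other.tcspc_resolution
            and self.tcspc_window == other.tcspc_window
        )


# ---------------------------------------------------------------------------
# photon stream container


def write_photon_stream(stream: PhotonStream, path: str | Path) -> None:
    """Write a stream to the single-file HDF5 container (schema v1)."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "flpaint-photon-stream"
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["tcspc_resolution_ns"] = stream.tcspc_resolution
        f.attrs["tcspc_window_ns"] = stream.tcspc_window
        geom = stream.geometry
        if isinstance(geom, CameraGeometry):
            f.attrs["geometry_kind"] = "camera"
            f.attrs["geometry"] = json.dumps(
                {
                    "sensor_pixels": list(geom.sensor_pixels),
                    "raw_pixel_size_at_sample": geom.raw_pixel_size_at_sample,
                    "spatial_binning": geom.spatial_binning,
                }
            )
        else:
            f.attrs["geometry_kind"] = "scan"
            f.attrs["geometry"] = json.dumps(
                {
                    "region_um": list(geom.region_um),
                    "pixel_size_nm": geom.pixel_size_nm,
                    "dwell_time_us": geom.dwell_time_us,
                    "frames_total": geom.frames_total,
                    "z_step_nm": geom.z_step_nm,
                }
            )
        f.attrs["metadata"] = json.dumps(stream.metadata)
        f.create_dataset("x", data=np.asarray(stream.x, dtype=np.float64))
        f.create_dataset("y", data=np.asarray(stream.y, dtype=np.float64))
        f.create_dataset("macro_time", data=np.asarray(stream.macro_time, dtype=np.float64))
        f.create_dataset("micro_time", data=np.asarray(stream.micro_time, dtype=np.float64))
        if stream.frame_index is not None:
            f.create_dataset("frame_index", data=np.asarray(stream.frame_index, dtype=np.int64))
        if stream.z_plane is not None:
            f.create_dataset("z_plane", data=np.asarray(stream.z_plane, dtype=np.int64))


def read_photon_stream(path: str | Path) -> PhotonStream:
    """Read a stream container; lossless inverse of :func:`write_photon_stream`."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:  # not an HDF5 file / truncated / wrong magic
        raise FormatError(f"{path}: not a readable photon-stream container ({exc})") from exc
    with f:
        if f.attrs.get("format") != "flpaint-photon-stream":
            raise FormatError(f"{path}: missing photon-stream format marker")
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"{path}: schema version mismatch (expected {SCHEMA_VERSION}, found {version})"
            )
        geom_info = json.loads(f.attrs["geometry"])
        if f.attrs["geometry_kind"] == "camera":
            geometry: CameraGeometry | ScanGeometry = CameraGeometry(
                sensor_pixels=tuple(geom_info["sensor_pixels"]),
                raw_pixel_size_at_sample=geom_info["raw_pixel_size_at_sample"],
                spatial_binning=geom_info["spatial_binning"],
            )
        else:
            geometry = ScanGeometry(
                region_um=tuple(geom_info["region_um"]),
                pixel_size_nm=geom_info["pixel_size_nm"],
                dwell_time_us=geom_info["dwell_time_us"],
                frames_total=geom_info["frames_total"],
                z_step_nm=geom_info["z_step_nm"],
            )
        return PhotonStream(
            x=f["x"][:],
            y=f["y"][:],
            macro_time=f["macro_time"][:],
            micro_time=f["micro_time"][:],
            frame_index=f["frame_index"][:] if "frame_index" in f else None,
            z_plane=f["z_plane"][:] if "z_plane" in f else None,
            geometry=geometry,
            tcspc_resolution=float(f.attrs["tcspc_resolution_ns"]),
            tcspc_window=float(f.attrs["tcspc_window_ns"]),
            metadata=json.loads(f.attrs["metadata"]),
        )


def read_time_tag_csv(
    path: str | Path,
    geometry: CameraGeometry | ScanGeometry,
    tcspc_resolution: float,
    tcspc_window: float,
) -> PhotonStream:
    """Import shim for generic time-tag tables.

    Expects columns ``x, y, macro_time_s, micro_time_ns`` and optionally
    ``frame_index`` / ``z_plane``.
    """
    df = pd.read_csv(path)
    needed = {"x", "y", "macro_time_s", "micro_time_ns"}
    missing = needed - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return PhotonStream(
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        macro_time=df["macro_time_s"].to_numpy(float),
        micro_time=df["micro_time_ns"].to_numpy(float),
        frame_index=df["frame_index"].to_numpy(np.int64) if "frame_index" in df else None,
        z_plane=df["z_plane"].to_numpy(np.int64) if "z_plane" in df else None,
        geometry=geometry,
        tcspc_resolution=tcspc_resolution,
        tcspc_window=tcspc_window,
    )


# ---------------------------------------------------------------------------
# localization tables


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    """Write a localization table as CSV (values kept to >= 9 significant digits)."""
    missing = [c for c in LOCALIZATION_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"localization table is missing mandatory columns {missing}")
    posterior_cols = sorted(
        (c for c in table.columns if c.startswith("posterior_p")),
        key=lambda c: int(c.removeprefix("posterior_p")),
    )
    cols = LOCALIZATION_COLUMNS + posterior_cols
    table[cols].to_csv(path, index=False, float_format="%.12g")


def read_localizations(path: str | Path) -> pd.DataFrame:
    """Read a localization CSV, validating the mandatory column set."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"{path}: not a readable localization CSV ({exc})") from exc
    missing = [c for c in LOCALIZATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    return df


# ---------------------------------------------------------------------------
# image export


def _lifetime_to_rgb(
    intensity: np.ndarray, lifetime: np.ndarray, limits: tuple[float, float]
) -> np.ndarray:
    """Map per-pixel mean lifetime to hue and intensity to value (HSV)."""
    from matplotlib.colors import hsv_to_rgb

    lo, hi = limits
    frac = np.clip((np.nan_to_num(lifetime, nan=lo) - lo) / max(hi - lo, 1e-12), 0.0, 1.0)
    # hue runs blue (short tau) -> red (long tau), spanning 2/3 of the wheel
    hsv = np.stack(
        [
            (1.0 - frac) * (2.0 / 3.0),
            np.ones_like(frac),
            intensity / intensity.max() if intensity.max() > 0 else np.zeros_like(intensity),
        ],
        axis=-1,
    )
    return hsv_to_rgb(hsv)


def export_image(rendered, path: str | Path, mode: str = "intensity") -> None:
    """Export a rendered image.

    ``mode='intensity'`` writes a 16-bit grayscale TIFF (linear scaling, the
    scale factor and pixel size stored in the TIFF description).
    ``mode='lifetime'`` writes an 8-bit RGB TIFF in which hue encodes the
    per-pixel mean lifetime; the colormap limits (ns) are stored in the
    description so the colorbar can be reproduced.
    """
    import tifffile

    path = Path(path)
    if mode == "intensity":
        img = np.asarray(rendered.intensity, dtype=np.float64)
        peak = img.max()
        scale = (65535.0 / peak) if peak > 0 else 1.0
        meta = {
            "mode": "intensity",
            "scale_counts_per_dn": 1.0 / scale,
            "render_pixel_size_nm": rendered.render_pixel_size,
        }
        tifffile.imwrite(path, (img * scale).astype(np.uint16), description=json.dumps(meta))
    elif mode == "lifetime":
        limits = tuple(rendered.colormap_limits)
        rgb = _lifetime_to_rgb(
            np.asarray(rendered.intensity, float), np.asarray(rendered.lifetime, float), limits
        )
        meta = {
            "mode": "lifetime",
            "colormap_limits_ns": list(limits),
            "render_pixel_size_nm": rendered.render_pixel_size,
        }
        tifffile.imwrite(path, (rgb * 255).astype(np.uint8), description=json.dumps(meta))
    else:
        raise ValueError(f"unknown export mode {mode!r} (expected 'intensity' or 'lifetime')")
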