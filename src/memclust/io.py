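"""Reading and writing TIFF images, CSV tables and JSON summaries.

All output tables carry unit-bearing column names (``_um2``, ``_s``,
``_AU``, ``_deg``) so downstream consumers never have to guess units.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .clusters import ClusterRecord
from .images import CalibratedImage, ImageStack
from .kinetics import FRAPCurve, Kymograph, LifetimeRecord
from .spt import MSDCurve, Trajectory

__all__ = [
    "load_image",
    "save_image",
    "clusters_to_csv",
    "tracks_to_csv",
    "msd_to_csv",
    "lifetimes_to_csv",
    "load_frap_csv",
    "load_angles_csv",
    "write_json",
]


def load_image(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
) -> CalibratedImage | ImageStack:
    """Read a single- or multi-page TIFF as a calibrated image or stack.

    TIFF files rarely carry reliable physical calibration, so the pixel
    size (and frame interval for stacks) must come from the caller;
    omitting them raises rather than silently assuming 1 µm/px.
    """
    arr = tifffile.imread(str(path))
    if pixel_size is None:
        raise ValueError(f"{path}: pixel_size (µm/px) must be provided")
    if arr.ndim == 2:
        return CalibratedImage(np.asarray(arr, dtype=float), pixel_size)
    if arr.ndim == 3:
        if frame_interval is None:
            raise ValueError(f"{path}: frame_interval (s) required for a stack")
        return ImageStack(np.asarray(arr, dtype=float), pixel_size, frame_interval)
    raise ValueError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")


def save_image(obj: CalibratedImage | ImageStack | Kymograph, path: str | Path) -> None:
    """Write pixels as float32 TIFF (lossless for the values we produce)."""
    if isinstance(obj, CalibratedImage):
        data = obj.pixels
    elif isinstance(obj, ImageStack):
        data = obj.frames
    elif isinstance(obj, Kymograph):
        data = obj.array
    else:
        raise TypeError(f"cannot save object of type {type(obj).__name__}")
    tifffile.imwrite(str(path), np.asarray(data, dtype=np.float32))


def clusters_to_csv(records: list[ClusterRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "label": [r.label for r in records],
            "area_um2": [r.area for r in records],
            "size_class": [r.size_class for r in records],
            "centroid_x_um": [r.centroid[0] for r in records],
            "centroid_y_um": [r.centroid[1] for r in records],
            "mean_AU": [r.mean_intensity for r in records],
            "total_AU": [r.total_intensity for r in records],
        }
    )
    df.to_csv(path, index=False)


def tracks_to_csv(tracks: list[Trajectory], path: str | Path) -> None:
    rows = []
    for i, tr in enumerate(tracks):
        for det in tr.detections:
            rows.append(
                {
                    "track_id": i,
                    "frame": det.frame,
                    "x_um": det.position[0],
                    "y_um": det.position[1],
                    "intensity_AU": det.total_intensity,
                    "label": tr.label or "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def msd_to_csv(curve: MSDCurve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "lag_s": curve.lags,
            "msd_um2": curve.msd,
            "se_um2": curve.se,
            "n_pairs": curve.n_pairs,
        }
    ).to_csv(path, index=False)


def lifetimes_to_csv(records: list[LifetimeRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "duration_s": [r.duration for r in records],
            "censored": [r.censored for r in records],
            "start_frame": [r.start_frame for r in records],
            "end_frame": [r.end_frame for r in records],
            "row": [r.row for r in records],
        }
    ).to_csv(path, index=False)


def load_frap_csv(path: str | Path) -> FRAPCurve:
    """Read a curve CSV with columns t_s and intensity_AU.

    Optional columns prebleach_AU and background_AU (constant) override
    the defaults (pre-bleach mean, 0).
    """
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy(dtype=float)
    y = df["intensity_AU"].to_numpy(dtype=float)
    bg = float(df["background_AU"].iloc[0]) if "background_AU" in df else 0.0
    if "prebleach_AU" in df:
        pre = float(df["prebleach_AU"].iloc[0])
    else:
        pre = float(y[t < 0].mean())
    return FRAPCurve(times=t, intensity=y, prebleach_level=pre, background=bg)


def load_angles_csv(path: str | Path) -> pd.DataFrame:
    """Angle table with columns angle_deg, condition and optional time_h."""
    df = pd.read_csv(path)
    if "angle_deg" not in df.columns:
        raise ValueError(f"{path}: missing angle_deg column")
    return df


def write_json(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o).__name__}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default))
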