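"""Root asymmetry and gravitropism summaries.

After a 90° reorientation, auxin and its transporters redistribute
toward the new lower side of the root; the lower/upper intensity ratio
along the meristem epidermis quantifies that asymmetry, and the deviated
root-tip angle quantifies the downstream gravitropic bending.  This
module measures sided intensity profiles on calibrated images, forms the
lower/upper ratio and treatment fold changes, and summarizes root-tip
angle tables (means, SEMs, two-sample t-tests, dose–response ordering).

Angle convention: angles are stored as signed deviations from the
vertical growth vector in degrees (positive = toward the gravity vector
after reorientation); summaries default to absolute deviations, which is
how bending magnitude is conventionally charted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from scipy.ndimage import map_coordinates
from skimage.draw import polygon as _sk_polygon

from .images import CalibratedImage

__all__ = [
    "IntensityProfile",
    "SidedProfile",
    "AsymmetryResult",
    "RegionIntensity",
    "AngleSample",
    "AngleSummary",
    "TTestResult",
    "measure_profile",
    "sided_ratio",
    "fold_change",
    "region_intensity",
    "angle_stats",
    "compare_conditions",
    "dose_response",
]


@dataclass(frozen=True)
class IntensityProfile:
    positions: np.ndarray  # µm along the line
    intensity: np.ndarray  # AU

    @property
    def mean(self) -> float:
        return float(self.intensity.mean())


@dataclass(frozen=True)
class SidedProfile:
    upper: IntensityProfile
    lower: IntensityProfile

    @property
    def mean_upper(self) -> float:
        return self.upper.mean

    @property
    def mean_lower(self) -> float:
        return self.lower.mean


@dataclass(frozen=True)
class AsymmetryResult:
    ratio_lower_upper: float
    fold_change_vs_control: float | None = None


@dataclass(frozen=True)
class RegionIntensity:
    region_label: str
    mean: float  # AU
    n_pixels: int


@dataclass(frozen=True)
class AngleSample:
    """Root-tip angles (degrees deviated from vertical) for one condition."""

    angles: np.ndarray
    condition: str = ""
    time_point: float | None = None  # h

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        if a.size < 1:
            raise ValueError("need at least one angle")
        if not np.all(np.isfinite(a)):
            raise ValueError("angles must be finite")
        object.__setattr__(self, "angles", a)


@dataclass(frozen=True)
class AngleSummary:
    mean: float  # degrees
    sem: float  # NaN when n = 1
    n: int


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    df: int


def measure_profile(
    image: CalibratedImage,
    line: np.ndarray,
    width: int = 1,
) -> IntensityProfile:
    """Mean intensity across ``width`` pixels at 1-px steps along a polyline.

    ``line`` is an (N, 2) array of (x, y) vertices in µm; sampling uses
    bilinear interpolation.  Positions are cumulative arc length in µm.
    """
    line = np.asarray(line, dtype=float)
    if line.ndim != 2 or line.shape[1] != 2 or line.shape[0] < 2:
        raise ValueError("line must be an (N≥2, 2) array of (x, y) µm vertices")
    ps = image.pixel_size
    h, w = image.shape
    pts = line[:, ::-1] / ps  # (row, col)
    if np.any(pts < 0) or np.any(pts[:, 0] > h - 1) or np.any(pts[:, 1] > w - 1):
        raise ValueError("polyline extends outside the image bounds")

    rows, cols, normals = [], [], []
    for a, b in zip(pts[:-1], pts[1:]):
        seg = b - a
        length = float(np.hypot(*seg))
        n_steps = max(1, int(round(length)))
        direction = seg / length if length > 0 else np.array([0.0, 1.0])
        normal = np.array([-direction[1], direction[0]])
        for t in np.arange(n_steps) / n_steps:
            p = a + t * seg
            rows.append(p[0])
            cols.append(p[1])
            normals.append(normal)
    rows.append(pts[-1][0])
    cols.append(pts[-1][1])
    normals.append(normals[-1])
    rows, cols, normals = np.array(rows), np.array(cols), np.array(normals)

    offsets = np.arange(width, dtype=float) - (width - 1) / 2.0
    acc = np.zeros(rows.size)
    for off in offsets:
        rr = np.clip(rows + off * normals[:, 0], 0, h - 1)
        cc = np.clip(cols + off * normals[:, 1], 0, w - 1)
        acc += map_coordinates(image.pixels, [rr, cc], order=1, mode="nearest")
    intensity = acc / offsets.size

    steps = np.hypot(np.diff(rows), np.diff(cols)) * ps
    positions = np.concatenate([[0.0], np.cumsum(steps)])
    return IntensityProfile(positions=positions, intensity=intensity)


def sided_ratio(profile_pair: SidedProfile) -> AsymmetryResult:
    """Lower/upper mean-intensity ratio of a sided profile pair."""
    mu, ml = profile_pair.mean_upper, profile_pair.mean_lower
    if mu <= 0:
        raise ValueError("upper-side mean must be > 0")
    if ml <= 0:
        raise ValueError("lower-side mean must be > 0")
    return AsymmetryResult(ratio_lower_upper=ml / mu)


def fold_change(treated: float, control: float) -> float:
    """treated / control; scale-invariant by construction."""
    if control <= 0:
        raise ValueError("control summary must be > 0")
    return float(treated) / float(control)


def region_intensity(
    image: CalibratedImage,
    region: np.ndarray,
    label: str = "custom",
) -> RegionIntensity:
    """Mean intensity over a polygon (vertices in µm) or boolean mask."""
    region = np.asarray(region)
    if region.dtype == bool:
        mask = region
        if mask.shape != image.shape:
            raise ValueError("mask shape must match image shape")
    else:
        verts = region.astype(float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise ValueError("polygon needs ≥ 3 (x, y) µm vertices")
        ps = image.pixel_size
        h, w = image.shape
        rr, cc = _sk_polygon(verts[:, 1] / ps, verts[:, 0] / ps, shape=(h, w))
        mask = np.zeros(image.shape, dtype=bool)
        mask[rr, cc] = True
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty region: polygon covers no pixels")
    return RegionIntensity(
        region_label=label,
        mean=float(image.pixels[mask].mean()),
        n_pixels=n,
    )


def angle_stats(sample: AngleSample, absolute: bool = True) -> AngleSummary:
    """Mean, SEM and n of deviated root-tip angles.

    ``absolute=True`` (default) summarizes |angle|, the bending
    magnitude; SEM is NaN for a single angle.
    """
    a = np.abs(sample.angles) if absolute else sample.angles
    n = a.size
    sem = float(a.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return AngleSummary(mean=float(a.mean()), sem=sem, n=n)


def compare_conditions(
    a: AngleSample | np.ndarray,
    b: AngleSample | np.ndarray,
) -> TTestResult:
    """Two-tailed Student's t-test assuming equal variances."""
    xa = a.angles if isinstance(a, AngleSample) else np.asarray(a, dtype=float)
    xb = b.angles if isinstance(b, AngleSample) else np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("need n ≥ 2 per group")
    pooled_ss = xa.var(ddof=1) * (xa.size - 1) + xb.var(ddof=1) * (xb.size - 1)
    if pooled_ss == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    res = _stats.ttest_ind(xa, xb, equal_var=True)
    return TTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=int(xa.size + xb.size - 2),
    )


def dose_response(summaries: dict[float, float] | list[tuple[float, float]]) -> pd.DataFrame:
    """Ordered dose-vs-mean-response table with a monotonicity flag.

    ``summaries`` maps dose → mean response (angle or clustering index).
    The returned frame is sorted by dose and carries ``monotone``
    (strictly monotone in either direction), ``direction`` and a least-
    squares ``slope`` in its ``attrs``.
    """
    items = list(summaries.items()) if isinstance(summaries, dict) else list(summaries)
    if len(items) < 2:
        raise ValueError("need ≥ 2 doses")
    doses = np.array([d for d, _ in items], dtype=float)
    if np.unique(doses).size != doses.size:
        raise ValueError("duplicate doses")
    means = np.array([m for _, m in items], dtype=float)
    order = np.argsort(doses)
    doses, means = doses[order], means[order]
    diffs = np.diff(means)
    increasing = bool(np.all(diffs > 0))
    decreasing = bool(np.all(diffs < 0))
    slope = float(np.polyfit(doses, means, 1)[0])
    df = pd.DataFrame({"dose": doses, "mean_response": means})
    df.attrs["monotone"] = increasing or decreasing
    df.attrs["direction"] = (
        "increasing" if increasing else "decreasing" if decreasing else "none"
    )
    df.attrs["slope"] = slope
    return df
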