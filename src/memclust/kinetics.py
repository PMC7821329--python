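"""Membrane-perpendicular dynamics: FRAP fitting and puncta lifetimes.

FRAP (fluorescence recovery after photobleaching) partitions a membrane
protein population into a mobile fraction, which re-populates the
bleached region, and a stable (immobile) fraction, which does not.  The
normalized recovery is modelled as a single exponential

    I(t) = I0 + (Iinf − I0) · (1 − exp(−k·t)),   t ≥ 0 (bleach at t = 0)

with mobile fraction (Iinf − I0)/(1 − I0) and stable fraction its
complement; the two sum to one by construction.

Kymographs (position × time images read out along a membrane line) turn
the residence of endocytic puncta into horizontal streaks; the length of
a supra-threshold run times the frame interval is the particle's
residence lifetime.  Runs touching the first or last frame are censored
(their true lifetime is only bounded from below) and excluded from
summary means under the default policy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit
from scipy.ndimage import map_coordinates

from .images import ImageStack

__all__ = [
    "FRAPCurve",
    "FRAPFit",
    "FRAPFitError",
    "Kymograph",
    "LifetimeRecord",
    "LifetimeSummary",
    "normalize_frap",
    "fit_frap",
    "extract_kymograph",
    "measure_lifetimes",
    "summarize_lifetimes",
]


@dataclass(frozen=True)
class FRAPCurve:
    """A recovery curve with the bleach at t = 0.

    Negative times are pre-bleach samples; at least one is required.
    ``normalized`` marks curves already mapped to the [0, 1] pre-bleach
    scale by :func:`normalize_frap`.
    """

    times: np.ndarray  # s
    intensity: np.ndarray  # AU, or normalized units
    prebleach_level: float  # AU (1.0 once normalized)
    background: float = 0.0  # AU (0.0 once normalized)
    normalized: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and intensity must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.any(t < 0):
            raise ValueError("curve needs at least one pre-bleach (t < 0) sample")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensity", y)

    @property
    def post_bleach(self) -> tuple[np.ndarray, np.ndarray]:
        sel = self.times >= 0
        return self.times[sel], self.intensity[sel]


@dataclass(frozen=True)
class FRAPFit:
    mobile_fraction: float
    stable_fraction: float
    rate_k: float  # 1/s
    residual_rms: float  # normalized units
    i0: float  # fitted post-bleach intercept
    i_inf: float  # fitted plateau

    def __post_init__(self) -> None:
        if abs(self.mobile_fraction + self.stable_fraction - 1.0) > 1e-12:
            raise ValueError("mobile + stable fractions must sum to 1")


class FRAPFitError(RuntimeError):
    """Non-convergent FRAP fit; carries the initial guesses and bounds used."""

    def __init__(self, message: str, p0, bounds):
        super().__init__(f"{message} (p0={p0}, bounds={bounds})")
        self.p0 = p0
        self.bounds = bounds


@dataclass(frozen=True)
class Kymograph:
    """Position × time intensity array sampled along a membrane line."""

    array: np.ndarray  # (n_positions, n_frames) AU
    frame_interval: float  # s
    pixel_size: float  # µm

    def __post_init__(self) -> None:
        a = np.asarray(self.array, dtype=float)
        if a.ndim != 2:
            raise ValueError("kymograph array must be 2-D (position × time)")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        object.__setattr__(self, "array", a)

    @property
    def n_frames(self) -> int:
        return self.array.shape[1]


@dataclass(frozen=True)
class LifetimeRecord:
    """One membrane-residence event read from a kymograph row."""

    duration: float  # s = (end − start + 1) × frame_interval
    censored: bool
    start_frame: int
    end_frame: int
    row: int = 0

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError("end_frame must be ≥ start_frame")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")


@dataclass(frozen=True)
class LifetimeSummary:
    mean: float  # s, over uncensored records (default policy)
    median: float  # s
    n: int  # uncensored count used
    n_censored: int


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

def normalize_frap(raw: FRAPCurve) -> FRAPCurve:
    """Map a raw curve to (I − background)/(prebleach − background).

    The pre-bleach plateau maps to 1 and the background to 0; idempotent
    on curves that are already normalized.
    """
    if raw.normalized:
        return raw
    denom = raw.prebleach_level - raw.background
    if denom <= 0:
        raise ValueError("prebleach level must exceed background")
    y = (raw.intensity - raw.background) / denom
    return FRAPCurve(
        times=raw.times,
        intensity=y,
        prebleach_level=1.0,
        background=0.0,
        normalized=True,
    )


def _recovery(t, i0, i_inf, k):
    return i0 + (i_inf - i0) * (1.0 - np.exp(-k * t))


def fit_frap(curve: FRAPCurve) -> FRAPFit:
    """Least-squares single-exponential fit of a normalized recovery.

    Requires ≥ 8 post-bleach samples.  Mobile fraction is
    (Iinf − I0)/(1 − I0), i.e. the recovered share of the bleached
    signal; it is clipped to [0, 1].
    """
    if not curve.normalized:
        curve = normalize_frap(curve)
    t, y = curve.post_bleach
    if t.size < 8:
        raise ValueError(f"need ≥ 8 post-bleach samples, got {t.size}")
    i0_guess = float(y[0])
    iinf_guess = float(np.mean(y[-max(3, t.size // 10):]))
    span = max(iinf_guess - i0_guess, 1e-6)
    # time at which half the recovery is reached → k guess
    half = i0_guess + 0.5 * span
    above = t[y >= half]
    k_guess = np.log(2.0) / float(above[0]) if above.size and above[0] > 0 else 1.0
    p0 = (i0_guess, iinf_guess, k_guess)
    bounds = ([-0.5, -0.5, 0.0], [1.5, 1.5, np.inf])
    if np.ptp(y) == 0:
        # perfectly flat: no recovery at all
        popt = (i0_guess, i0_guess, 0.0)
    else:
        try:
            popt, _ = curve_fit(_recovery, t, y, p0=p0, bounds=bounds, maxfev=20_000)
        except RuntimeError as exc:
            raise FRAPFitError(str(exc), p0, bounds) from exc
    i0, i_inf, k = (float(v) for v in popt)
    denom = 1.0 - i0
    mobile = (i_inf - i0) / denom if denom > 1e-9 else 1.0
    mobile = float(np.clip(mobile, 0.0, 1.0))
    resid = y - _recovery(t, *popt)
    return FRAPFit(
        mobile_fraction=mobile,
        stable_fraction=1.0 - mobile,
        rate_k=max(k, 0.0),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        i0=i0,
        i_inf=i_inf,
    )


# ---------------------------------------------------------------------------
# kymographs and lifetimes
# ---------------------------------------------------------------------------

def extract_kymograph(
    stack: ImageStack,
    line: np.ndarray,
    width: int = 1,
) -> Kymograph:
    """Sample intensity along a polyline for every frame.

    ``line`` is an (N, 2) array of (x, y) vertices in µm.  The polyline
    is sampled at 1-pixel steps with bilinear interpolation; at each
    sample the maximum over ``width`` pixels perpendicular to the local
    direction is taken, so a punctum slightly off the line is not lost.
    """
    line = np.asarray(line, dtype=float)
    if line.ndim != 2 or line.shape[1] != 2 or line.shape[0] < 2:
        raise ValueError("line must be an (N≥2, 2) array of (x, y) µm vertices")
    ps = stack.pixel_size
    h, w = stack.frames.shape[1:]
    pts_px = line[:, ::-1] / ps  # (row, col) order
    if np.any(pts_px < 0) or np.any(pts_px[:, 0] > h - 1) or np.any(pts_px[:, 1] > w - 1):
        raise ValueError("polyline extends outside the image bounds")

    # resample polyline at ~1 px arc-length steps
    rows, cols, normals = [], [], []
    for a, b in zip(pts_px[:-1], pts_px[1:]):
        seg = b - a
        length = float(np.hypot(*seg))
        n_steps = max(1, int(round(length)))
        ts = np.arange(n_steps) / max(n_steps, 1)
        direction = seg / length if length > 0 else np.array([0.0, 1.0])
        normal = np.array([-direction[1], direction[0]])
        for t in ts:
            p = a + t * seg
            rows.append(p[0])
            cols.append(p[1])
            normals.append(normal)
    rows.append(pts_px[-1][0])
    cols.append(pts_px[-1][1])
    normals.append(normals[-1])
    rows = np.array(rows)
    cols = np.array(cols)
    normals = np.array(normals)

    offsets = np.arange(width, dtype=float) - (width - 1) / 2.0
    n_pos = rows.size
    out = np.zeros((n_pos, stack.n_frames))
    for t in range(stack.n_frames):
        frame = stack.frames[t]
        vals = np.full((offsets.size, n_pos), -np.inf)
        for i, off in enumerate(offsets):
            rr = np.clip(rows + off * normals[:, 0], 0, h - 1)
            cc = np.clip(cols + off * normals[:, 1], 0, w - 1)
            vals[i] = map_coordinates(frame, [rr, cc], order=1, mode="nearest")
        out[:, t] = vals.max(axis=0)
    return Kymograph(array=out, frame_interval=stack.frame_interval, pixel_size=ps)


def measure_lifetimes(
    kymo: Kymograph,
    intensity_threshold: float,
    min_frames: int = 1,
) -> list[LifetimeRecord]:
    """Residence lifetimes from contiguous supra-threshold runs per row.

    Each spatial row is assumed to host at most one particle at a time;
    separate visits are split by sub-threshold gaps of ≥ 1 frame.  Runs
    touching the first or last frame are flagged censored.  Runs shorter
    than ``min_frames`` are discarded as noise.
    """
    a = kymo.array
    n_frames = a.shape[1]
    records: list[LifetimeRecord] = []
    for row in range(a.shape[0]):
        above = a[row] >= intensity_threshold
        if not above.any():
            continue
        # run-length encode
        edges = np.flatnonzero(np.diff(above.astype(np.int8)))
        starts = [0] if above[0] else []
        starts += [int(e) + 1 for e in edges if above[e + 1]]
        ends = [int(e) for e in edges if above[e]]
        if above[-1]:
            ends.append(n_frames - 1)
        for s, e in zip(starts, ends):
            n = e - s + 1
            if n < min_frames:
                continue
            records.append(
                LifetimeRecord(
                    duration=n * kymo.frame_interval,
                    censored=(s == 0 or e == n_frames - 1),
                    start_frame=s,
                    end_frame=e,
                    row=row,
                )
            )
    return records


def summarize_lifetimes(
    records: list[LifetimeRecord],
    policy: str = "drop_censored",
) -> LifetimeSummary:
    """Mean/median lifetime, excluding censored records by default.

    ``policy="include_censored"`` treats censored durations as exact —
    a lower-bound summary, reported for completeness only.
    """
    if policy not in ("drop_censored", "include_censored"):
        raise ValueError(f"unknown policy {policy!r}")
    n_cens = sum(r.censored for r in records)
    if policy == "drop_censored":
        durs = [r.duration for r in records if not r.censored]
        if not durs:
            raise ValueError(
                "all records are censored; no uncensored lifetime to summarize"
            )
    else:
        durs = [r.duration for r in records]
        if not durs:
            raise ValueError("no records")
    d = np.asarray(durs)
    return LifetimeSummary(
        mean=float(d.mean()),
        median=float(np.median(d)),
        n=int(d.size),
        n_censored=int(n_cens),
    )
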