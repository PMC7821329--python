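"""Single-particle tracking: spot detection, linking, MSD and diffusion.

The workflow mirrors TIRF-style membrane-particle analysis: detect
diffraction-limited spots frame by frame, link them into trajectories by
nearest-neighbour association, classify each spot by total intensity
(a proxy for oligomeric state), compute the time-averaged mean squared
displacement per region of interest and fit the short-lag MSD with a
line whose slope/4 is the 2-D diffusion coefficient.  The fit intercept
is retained as the localization-noise term: static localization error of
sd σ per axis offsets the 2-D MSD by 4σ².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import peak_local_max

from .images import CalibratedImage

__all__ = [
    "SpotDetection",
    "Trajectory",
    "MSDCurve",
    "DiffusionEstimate",
    "INTENSITY_CLASSES",
    "INTENSITY_EDGES_AU",
    "detect_spots",
    "classify_intensity",
    "link_trajectories",
    "compute_msd",
    "fit_diffusion",
    "diffusion_distribution",
]

#: Intensity classes for membrane particles, in increasing brightness order.
INTENSITY_CLASSES = ("low", "medium", "high")

#: Class boundaries in AU: low < 5e3 ≤ medium ≤ 15e3 < high.
INTENSITY_EDGES_AU = (5_000.0, 15_000.0)


@dataclass(frozen=True)
class SpotDetection:
    frame: int
    position: tuple[float, float]  # (x, y) µm
    total_intensity: float  # background-subtracted AU


@dataclass
class Trajectory:
    """Linked detections ordered by strictly increasing frame index."""

    detections: list[SpotDetection]
    frame_interval: float  # s
    label: str | None = None  # optional ground-truth / mobility label

    def __post_init__(self) -> None:
        frames = [d.frame for d in self.detections]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("detection frames must be strictly increasing")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        return np.array([d.position for d in self.detections], dtype=float)

    @property
    def mean_intensity(self) -> float:
        return float(np.mean([d.total_intensity for d in self.detections]))


@dataclass(frozen=True)
class MSDCurve:
    lags: np.ndarray  # s, strictly increasing
    msd: np.ndarray  # µm²
    se: np.ndarray  # µm², standard error across tracks
    n_pairs: np.ndarray  # displacement pairs contributing per lag
    n_tracks: np.ndarray = field(default=None)  # tracks contributing per lag


@dataclass(frozen=True)
class DiffusionEstimate:
    D: float  # µm²/s, ≥ 0 after clipping
    intercept: float  # µm², localization-noise term
    fit_lags: tuple[float, float]  # (first, last) lag used, s
    r_squared: float
    clipped: bool = False  # True when a negative slope was clipped to 0


# ---------------------------------------------------------------------------
# detection and classification
# ---------------------------------------------------------------------------

def detect_spots(
    frame: CalibratedImage,
    expected_radius: float,
    snr_min: float = 5.0,
) -> list[SpotDetection]:
    """Detect diffraction-limited spots in one frame.

    Local maxima above background + snr_min × noise (robust MAD scale)
    are refined to sub-pixel centroids over a window of ±2 radii, and the
    background-subtracted intensity is summed over the same window.
    ``expected_radius`` is the approximate spot radius in µm.
    """
    px = frame.pixels
    ps = frame.pixel_size
    r_px = max(1, int(np.ceil(expected_radius / ps - 1e-9)))
    bg = float(np.median(px))
    noise = 1.4826 * float(np.median(np.abs(px - bg)))
    thr = bg + snr_min * noise + 1e-12
    if px.max() < thr:
        return []
    coords = peak_local_max(px, min_distance=r_px, threshold_abs=thr)
    # window must cover the spot tails, or truncation biases the centroid
    w = max(3, int(np.ceil(2.5 * expected_radius / ps)))
    h, wd = px.shape
    out: list[SpotDetection] = []
    for row, col in coords:
        r0, r1 = max(0, row - w), min(h, row + w + 1)
        c0, c1 = max(0, col - w), min(wd, col + w + 1)
        win = px[r0:r1, c0:c1] - bg
        win = np.clip(win, 0, None)
        total = float(win.sum())
        if total <= 0:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        cy = float((rr * win).sum() / total)
        cx = float((cc * win).sum() / total)
        out.append(
            SpotDetection(frame=0, position=(cx * ps, cy * ps), total_intensity=total)
        )
    return out


def classify_intensity(spot: SpotDetection | float) -> str:
    """Intensity class of a spot: low < 5×10³ ≤ medium ≤ 15×10³ < high (AU)."""
    total = spot.total_intensity if isinstance(spot, SpotDetection) else float(spot)
    if total < 0:
        raise ValueError(f"total_intensity must be ≥ 0, got {total}")
    if total < INTENSITY_EDGES_AU[0]:
        return "low"
    if total <= INTENSITY_EDGES_AU[1]:
        return "medium"
    return "high"


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def link_trajectories(
    detections: list[list[SpotDetection]],
    max_disp: float,
    max_gap: int = 0,
    frame_interval: float = 1.0,
) -> list[Trajectory]:
    """Greedy nearest-neighbour linking of per-frame detections.

    Candidate links between active track ends and new detections are
    sorted by distance and accepted greedily, each detection used at most
    once; a track stays active through up to ``max_gap`` missing frames.
    Adequate at low particle densities, where the shortest link is almost
    always the true one.
    """
    tracks: list[list[SpotDetection]] = []
    active: list[int] = []  # indices into tracks
    for t, dets in enumerate(detections):
        dets = [
            SpotDetection(frame=t, position=d.position, total_intensity=d.total_intensity)
            for d in dets
        ]
        # drop tracks whose last frame is too old
        active = [i for i in active if t - tracks[i][-1].frame <= max_gap + 1]
        candidates = []
        for i in active:
            last = tracks[i][-1]
            for j, d in enumerate(dets):
                dist = float(np.hypot(
                    d.position[0] - last.position[0],
                    d.position[1] - last.position[1],
                ))
                if dist <= max_disp:
                    candidates.append((dist, i, j))
        candidates.sort(key=lambda c: c[0])
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, i, j in candidates:
            if i in used_tracks or j in used_dets:
                continue
            tracks[i].append(dets[j])
            used_tracks.add(i)
            used_dets.add(j)
        for j, d in enumerate(dets):
            if j not in used_dets:
                tracks.append([d])
                active.append(len(tracks) - 1)
    return [Trajectory(detections=tr, frame_interval=frame_interval) for tr in tracks]


# ---------------------------------------------------------------------------
# MSD and diffusion
# ---------------------------------------------------------------------------

def _track_tamsd(track: Trajectory, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD of one track for lags 1..max_lag (frames).

    Returns (msd, n_pairs); lags with no pair (because of gaps) get NaN.
    """
    frames = track.frames
    pos = track.positions
    idx = {f: i for i, f in enumerate(frames)}
    msd = np.full(max_lag, np.nan)
    npairs = np.zeros(max_lag, dtype=int)
    for lag in range(1, max_lag + 1):
        sq = []
        for f, i in idx.items():
            k = idx.get(f + lag)
            if k is not None:
                d = pos[k] - pos[i]
                sq.append(d[0] * d[0] + d[1] * d[1])
        if sq:
            msd[lag - 1] = float(np.mean(sq))
            npairs[lag - 1] = len(sq)
    return msd, npairs


def compute_msd(
    tracks: list[Trajectory],
    min_length: int = 5,
    max_lag: int | None = None,
) -> MSDCurve:
    """Ensemble mean of time-averaged MSDs over the tracks of one ROI.

    Each qualifying track (≥ ``min_length`` detections) contributes its
    time-averaged MSD; the curve is the across-track mean with its
    standard error.  ``max_lag`` defaults to a quarter of the longest
    track, the usual guard against the noisy long-lag tail.
    """
    tracks = [t for t in tracks if len(t) >= min_length]
    if not tracks:
        raise ValueError(f"no tracks with ≥ {min_length} detections")
    dt = tracks[0].frame_interval
    if any(t.frame_interval != dt for t in tracks):
        raise ValueError("tracks must share one frame_interval")
    longest = max(int(t.frames[-1] - t.frames[0]) for t in tracks)
    if max_lag is None:
        max_lag = max(1, longest // 4)
    max_lag = min(max_lag, longest)
    per_track = np.full((len(tracks), max_lag), np.nan)
    pairs = np.zeros(max_lag, dtype=int)
    for i, tr in enumerate(tracks):
        m, np_ = _track_tamsd(tr, max_lag)
        per_track[i] = m
        pairs += np_
    n_tracks = np.sum(~np.isnan(per_track), axis=0)
    keep = n_tracks > 0
    sub = per_track[:, keep]
    nt = n_tracks[keep]
    mean = np.nansum(sub, axis=0) / nt
    ss = np.nansum((sub - mean) ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(ss / np.where(nt > 1, nt - 1, 1))
        se = np.where(nt > 1, sd / np.sqrt(nt), np.nan)
    lags = (np.arange(1, max_lag + 1)[keep]) * dt
    return MSDCurve(
        lags=lags,
        msd=mean,
        se=se,
        n_pairs=pairs[keep],
        n_tracks=nt,
    )


def fit_diffusion(curve: MSDCurve, n_fit_lags: int = 4) -> DiffusionEstimate:
    """Weighted least-squares line through the first ``n_fit_lags`` lags.

    D = slope / 4 for 2-D diffusion; the intercept is kept as the
    localization-noise offset (4σ² for static error σ per axis).  Weights
    are 1/SE² when SEs are available, uniform otherwise.  A negative
    slope is clipped to D = 0 and flagged.
    """
    if len(curve.lags) < n_fit_lags:
        raise ValueError(
            f"curve has {len(curve.lags)} lags, need ≥ {n_fit_lags}"
        )
    x = np.asarray(curve.lags[:n_fit_lags], dtype=float)
    y = np.asarray(curve.msd[:n_fit_lags], dtype=float)
    se = np.asarray(curve.se[:n_fit_lags], dtype=float)
    if np.all(np.isfinite(se)) and np.all(se > 0):
        w = 1.0 / se**2
    else:
        w = np.ones_like(x)
    W = np.sum(w)
    xb = np.sum(w * x) / W
    yb = np.sum(w * y) / W
    sxx = np.sum(w * (x - xb) ** 2)
    if sxx == 0:
        raise ValueError("degenerate lag axis")
    slope = float(np.sum(w * (x - xb) * (y - yb)) / sxx)
    intercept = float(yb - slope * xb)
    yhat = intercept + slope * x
    sst = float(np.sum(w * (y - yb) ** 2))
    r2 = 1.0 - float(np.sum(w * (y - yhat) ** 2)) / sst if sst > 0 else 1.0
    clipped = slope < 0
    D = 0.0 if clipped else slope / 4.0
    return DiffusionEstimate(
        D=D,
        intercept=intercept,
        fit_lags=(float(x[0]), float(x[-1])),
        r_squared=r2,
        clipped=clipped,
    )


def diffusion_distribution(
    estimates: list[DiffusionEstimate],
    bin_edges: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram of per-ROI diffusion coefficients.

    Returns (bin_edges, frequencies) with frequencies summing to 1.
    Default bins span 0 to slightly above the largest estimate in 20 steps.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    d = np.array([e.D for e in estimates], dtype=float)
    if bin_edges is None:
        top = d.max() * 1.05 if d.max() > 0 else 1e-3
        bin_edges = np.linspace(0.0, top, 21)
    counts, edges = np.histogram(d, bins=bin_edges)
    freqs = counts / counts.sum()
    return edges, freqs
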