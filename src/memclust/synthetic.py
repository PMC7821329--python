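"""Seeded synthetic-data generators with ground truth.

Each generator emulates the statistical structure one analysis stage
assumes — cluster fields with controlled area distributions, mixtures of
Brownian and immobile trajectories, single-exponential FRAP recoveries,
kymographs of exponentially lived puncta, and two-sided root fields with
an imposed fold difference — and returns the planted ground truth next
to the rendered data.  Every generator is a pure function of its spec,
seed included: the same spec yields bit-identical output.

Camera noise follows the standard two-stage model: Poisson shot noise
(scaled by ``poisson_scale`` AU per photon) followed by additive
Gaussian read noise; both stages are optional so tests can run
noise-free.  Units are µm, s and AU throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .clusters import SIZE_BIN_EDGES, SIZE_CLASSES, ClusterRecord, classify_cluster_size
from .images import CalibratedImage, ImageStack
from .kinetics import FRAPCurve, Kymograph, LifetimeRecord
from .spt import SpotDetection, Trajectory

__all__ = [
    "ClusterFieldSpec",
    "TrajectoryFieldSpec",
    "FRAPSpec",
    "KymographSpec",
    "AsymmetryFieldSpec",
    "ClusterPlacementError",
    "generate_cluster_image",
    "generate_trajectories",
    "render_trajectory_stack",
    "generate_frap_curve",
    "generate_kymograph",
    "generate_asymmetric_root",
]

#: Gaussian-blob geometry: area at half maximum = 2π ln2 σ².
_FWHM_AREA_FACTOR = 2.0 * np.pi * np.log(2.0)


class ClusterPlacementError(RuntimeError):
    """Raised when non-overlapping cluster placement fails; the requested
    density exceeds what the field can host."""


def _apply_camera_noise(
    img: np.ndarray, rng: np.random.Generator, poisson_scale: float, gaussian_sd: float
) -> np.ndarray:
    if poisson_scale > 0:
        img = rng.poisson(np.clip(img, 0, None) / poisson_scale) * poisson_scale
    if gaussian_sd > 0:
        img = img + rng.normal(0.0, gaussian_sd, size=img.shape)
    return np.clip(img, 0.0, None)


# ---------------------------------------------------------------------------
# cluster fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterFieldSpec:
    """A membrane field carrying Gaussian-profiled clusters.

    ``area_distribution`` names how cluster areas (µm², defined at half
    maximum) are drawn:

    - ``{"kind": "lognormal", "mu": ..., "sigma": ...}`` — log-space
      parameters of the area;
    - ``{"kind": "class_mixture", "probs": {class: p, ...}}`` — pick a
      size class with the given probabilities, then draw the area
      uniformly inside that class's bin (the unbounded "long" bin is
      capped at 2 µm²).

    ``membrane_geometry`` restricts placement to a horizontal band of
    rows ``{"kind": "band", "row_start": r0, "row_stop": r1}``; ``None``
    uses the full frame.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.05  # µm/pixel
    n_clusters: int = 100
    area_distribution: dict = field(
        default_factory=lambda: {"kind": "lognormal", "mu": np.log(0.3), "sigma": 0.5}
    )
    cluster_peak_intensity: float = 1000.0  # AU above background
    background_intensity: float = 100.0  # AU
    poisson_scale: float = 0.0  # AU per photon; 0 disables shot noise
    gaussian_sd: float = 0.0  # AU read noise; 0 disables
    membrane_geometry: dict | None = None
    min_separation_factor: float = 2.0  # centre distance ≥ factor × (r1 + r2)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be ≥ 0")
        if self.cluster_peak_intensity < 0 or self.background_intensity < 0:
            raise ValueError("intensities must be ≥ 0")


def _draw_areas(dist: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist.get("kind")
    if kind == "lognormal":
        return rng.lognormal(dist["mu"], dist["sigma"], size=n)
    if kind == "class_mixture":
        probs = dist["probs"]
        classes = list(probs)
        p = np.array([probs[c] for c in classes], dtype=float)
        p = p / p.sum()
        edges = {
            "tiny": (0.02, SIZE_BIN_EDGES[0]),
            "small": (SIZE_BIN_EDGES[0], SIZE_BIN_EDGES[1]),
            "medium": (SIZE_BIN_EDGES[1], SIZE_BIN_EDGES[2]),
            "long": (SIZE_BIN_EDGES[2], float(dist.get("long_cap", 2.0))),
        }
        for c in classes:
            if c not in SIZE_CLASSES:
                raise ValueError(f"unknown size class {c!r}")
        picks = rng.choice(len(classes), size=n, p=p)
        lo = np.array([edges[classes[i]][0] for i in picks])
        hi = np.array([edges[classes[i]][1] for i in picks])
        return lo + (hi - lo) * rng.random(n)
    raise ValueError(f"unknown area distribution kind {dist.get('kind')!r}")


def generate_cluster_image(
    spec: ClusterFieldSpec,
) -> tuple[CalibratedImage, list[ClusterRecord]]:
    """Render a cluster field and return it with its planted ground truth.

    Clusters are Gaussian blobs whose half-maximum footprint equals the
    drawn area (σ = √(area / 2π ln2)); centres are rejection-sampled so
    half-maximum discs stay separated, keeping truth recoverable by
    thresholding at half maximum.  Ground truth records centroid, area,
    size class and the noise-free intensity over the half-maximum disc.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    ps = spec.pixel_size
    img = np.full((h, w), float(spec.background_intensity))
    if spec.n_clusters == 0:
        pixels = _apply_camera_noise(img, rng, spec.poisson_scale, spec.gaussian_sd)
        return CalibratedImage(pixels, ps), []

    areas = _draw_areas(spec.area_distribution, spec.n_clusters, rng)
    sigmas_px = np.sqrt(areas / _FWHM_AREA_FACTOR) / ps
    radii_px = sigmas_px * np.sqrt(2.0 * np.log(2.0))  # half-maximum radius

    geom = spec.membrane_geometry
    if geom is None:
        r_lo, r_hi = 0, h
    elif geom.get("kind") == "band":
        r_lo, r_hi = int(geom["row_start"]), int(geom["row_stop"])
        if not 0 <= r_lo < r_hi <= h:
            raise ValueError("membrane band outside image")
    else:
        raise ValueError(f"unknown membrane_geometry {geom!r}")

    centres = np.empty((spec.n_clusters, 2))  # (row, col)
    max_attempts = 200 * spec.n_clusters + 1000
    attempts = 0
    placed = 0
    while placed < spec.n_clusters:
        if attempts >= max_attempts:
            raise ClusterPlacementError(
                f"placed only {placed}/{spec.n_clusters} non-overlapping clusters "
                f"after {attempts} attempts; requested density exceeds the "
                f"{h}×{w} px field (band rows {r_lo}–{r_hi})"
            )
        attempts += 1
        margin = radii_px[placed] + 1
        row = rng.uniform(r_lo + margin, r_hi - margin)
        col = rng.uniform(margin, w - margin)
        if placed:
            d = np.hypot(
                centres[:placed, 0] - row, centres[:placed, 1] - col
            )
            if np.any(d < spec.min_separation_factor * (radii_px[:placed] + radii_px[placed])):
                continue
        centres[placed] = (row, col)
        placed += 1

    yy, xx = np.mgrid[0:h, 0:w]
    truth: list[ClusterRecord] = []
    for i in range(spec.n_clusters):
        row, col = centres[i]
        sig = sigmas_px[i]
        r_half = radii_px[i]
        # render within a bounded window for speed
        ext = int(np.ceil(4 * sig)) + 1
        r0, r1 = max(0, int(row) - ext), min(h, int(row) + ext + 1)
        c0, c1 = max(0, int(col) - ext), min(w, int(col) + ext + 1)
        d2 = (yy[r0:r1, c0:c1] - row) ** 2 + (xx[r0:r1, c0:c1] - col) ** 2
        blob = spec.cluster_peak_intensity * np.exp(-d2 / (2 * sig * sig))
        img[r0:r1, c0:c1] += blob
        inside = d2 <= r_half * r_half
        disc = blob[inside] + spec.background_intensity
        truth.append(
            ClusterRecord(
                label=i + 1,
                area=float(areas[i]),
                centroid=(float(col * ps), float(row * ps)),
                mean_intensity=float(disc.mean()) if disc.size else float(
                    spec.cluster_peak_intensity + spec.background_intensity
                ),
                total_intensity=float(disc.sum()) if disc.size else float(
                    spec.cluster_peak_intensity + spec.background_intensity
                ),
                size_class=classify_cluster_size(float(areas[i])),
            )
        )
    pixels = _apply_camera_noise(img, rng, spec.poisson_scale, spec.gaussian_sd)
    return CalibratedImage(pixels, ps), truth


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryFieldSpec:
    """A mixture of free Brownian and immobile membrane particles.

    Free tracks take 2-D Gaussian steps with per-axis variance
    2·D_free·Δt and reflect at the field edges; immobile tracks jitter
    around a fixed anchor by the localization error only.  Every
    reported position carries localization noise of sd
    ``localization_sd`` per axis.  ``intensity_means`` assigns mean
    total spot intensity (AU) per mobility class, mirroring the
    brighter-oligomer / less-mobile phenomenology.
    """

    n_tracks: int = 100
    frame_interval: float = 0.1  # s
    n_frames: int = 60
    D_free: float = 0.05  # µm²/s
    immobile_fraction: float = 0.0
    localization_sd: float = 0.02  # µm per axis
    intensity_means: dict = field(
        default_factory=lambda: {"free": 3_000.0, "immobile": 20_000.0}
    )
    intensity_sd_fraction: float = 0.1
    field_size: float = 20.0  # µm (square field)
    pixel_size: float = 0.1  # µm/px, used when rendering a stack
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.immobile_fraction <= 1:
            raise ValueError("immobile_fraction must be in [0, 1]")
        if self.D_free < 0:
            raise ValueError("D_free must be ≥ 0")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 2:
            raise ValueError("need ≥ 2 frames")


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (billiard boundaries)."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


def generate_trajectories(spec: TrajectoryFieldSpec) -> list[Trajectory]:
    """Simulate labelled trajectories; labels are "free" or "immobile"."""
    rng = np.random.default_rng(spec.seed)
    n_imm = int(round(spec.immobile_fraction * spec.n_tracks))
    labels = ["immobile"] * n_imm + ["free"] * (spec.n_tracks - n_imm)
    dt = spec.frame_interval
    step_sd = np.sqrt(2.0 * spec.D_free * dt)
    out: list[Trajectory] = []
    for label in labels:
        start = rng.uniform(0, spec.field_size, size=2)
        if label == "free" and step_sd > 0:
            steps = rng.normal(0.0, step_sd, size=(spec.n_frames - 1, 2))
            true_pos = start + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
            true_pos = _reflect(true_pos, 0.0, spec.field_size)
        else:
            true_pos = np.tile(start, (spec.n_frames, 1))
        if spec.localization_sd > 0:
            obs = true_pos + rng.normal(0.0, spec.localization_sd, size=true_pos.shape)
        else:
            obs = true_pos
        mean_int = float(spec.intensity_means[label])
        ints = np.clip(
            rng.normal(mean_int, spec.intensity_sd_fraction * mean_int, spec.n_frames),
            0.0,
            None,
        )
        dets = [
            SpotDetection(frame=t, position=(float(obs[t, 0]), float(obs[t, 1])),
                          total_intensity=float(ints[t]))
            for t in range(spec.n_frames)
        ]
        out.append(Trajectory(detections=dets, frame_interval=dt, label=label))
    return out


def render_trajectory_stack(
    spec: TrajectoryFieldSpec,
    tracks: list[Trajectory],
    spot_sigma: float = 0.15,  # µm
    background: float = 100.0,
) -> ImageStack:
    """Render tracks as Gaussian spots into a time-lapse stack.

    Spot peak amplitude is chosen so the integrated (background-
    subtracted) intensity equals the detection's total_intensity.
    """
    ps = spec.pixel_size
    npx = int(round(spec.field_size / ps))
    sig_px = spot_sigma / ps
    frames = np.full((spec.n_frames, npx, npx), float(background))
    yy, xx = np.mgrid[0:npx, 0:npx]
    for tr in tracks:
        for det in tr.detections:
            x_px = det.position[0] / ps
            y_px = det.position[1] / ps
            peak = det.total_intensity / (2 * np.pi * sig_px * sig_px)
            ext = int(np.ceil(4 * sig_px)) + 1
            r0, r1 = max(0, int(y_px) - ext), min(npx, int(y_px) + ext + 1)
            c0, c1 = max(0, int(x_px) - ext), min(npx, int(x_px) + ext + 1)
            if r0 >= r1 or c0 >= c1:
                continue
            d2 = (yy[r0:r1, c0:c1] - y_px) ** 2 + (xx[r0:r1, c0:c1] - x_px) ** 2
            frames[det.frame, r0:r1, c0:c1] += peak * np.exp(-d2 / (2 * sig_px**2))
    return ImageStack(frames=frames, pixel_size=ps, frame_interval=spec.frame_interval)


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FRAPSpec:
    """Single-exponential recovery with a mobile fraction.

    The noise-free normalized expectation is
    I(t) = I0 + mobile·(1 − I0)·(1 − e^(−k t)) with
    I0 = 1 − bleach_depth, matching the model fitted by
    :func:`memclust.kinetics.fit_frap`.
    """

    prebleach_level: float = 1000.0  # AU
    bleach_depth: float = 0.8  # fraction of prebleach removed at t=0
    mobile_fraction: float = 0.7
    rate_k: float = 0.2  # 1/s
    duration: float = 60.0  # s post-bleach
    sample_interval: float = 0.5  # s
    n_prebleach: int = 5
    background: float = 0.0  # AU
    noise_sd: float = 0.0  # AU
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mobile_fraction <= 1:
            raise ValueError("mobile_fraction must be in [0, 1]")
        if self.rate_k < 0:
            raise ValueError("rate_k must be ≥ 0")
        if not 0 < self.bleach_depth <= 1:
            raise ValueError("bleach_depth must be in (0, 1]")


def generate_frap_curve(spec: FRAPSpec) -> FRAPCurve:
    """Simulate a raw FRAP curve (AU scale) with known true parameters."""
    rng = np.random.default_rng(spec.seed)
    pre_t = -spec.sample_interval * np.arange(spec.n_prebleach, 0, -1)
    post_t = np.arange(0.0, spec.duration + 1e-9, spec.sample_interval)
    t = np.concatenate([pre_t, post_t])
    i0 = 1.0 - spec.bleach_depth
    i_inf = i0 + spec.mobile_fraction * (1.0 - i0)
    norm = np.where(
        t < 0,
        1.0,
        i0 + (i_inf - i0) * (1.0 - np.exp(-spec.rate_k * np.clip(t, 0, None))),
    )
    span = spec.prebleach_level - spec.background
    raw = spec.background + span * norm
    if spec.noise_sd > 0:
        raw = raw + rng.normal(0.0, spec.noise_sd, size=raw.shape)
    return FRAPCurve(
        times=t,
        intensity=raw,
        prebleach_level=spec.prebleach_level,
        background=spec.background,
    )


# ---------------------------------------------------------------------------
# kymographs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KymographSpec:
    """Puncta with exponential residence lifetimes on a kymograph.

    Each particle occupies its own spatial row for one contiguous span.
    A lifetime drawn longer than fits in the movie runs to the last
    frame and is flagged censored; otherwise the span is placed fully
    inside the movie (uniform over interior start frames), so the
    uncensored ground-truth durations are an essentially unbiased sample
    of the exponential.
    """

    duration: float = 90.0  # s
    frame_interval: float = 0.3  # s
    n_particles: int = 50
    mean_lifetime: float = 8.0  # s
    particle_intensity: float = 500.0  # AU above background
    background: float = 50.0  # AU
    noise_sd: float = 0.0  # AU
    pixel_size: float = 0.1  # µm per row
    rows_per_particle: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if not self.mean_lifetime > 0:
            raise ValueError("mean_lifetime must be > 0")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0")


def generate_kymograph(
    spec: KymographSpec,
) -> tuple[Kymograph, list[LifetimeRecord]]:
    """Render a kymograph and its ground-truth lifetime records."""
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration / spec.frame_interval))
    n_rows = max(1, spec.n_particles)
    arr = np.full((n_rows, n_frames), float(spec.background))
    truth: list[LifetimeRecord] = []
    for i in range(spec.n_particles):
        life_s = rng.exponential(spec.mean_lifetime)
        n_live = max(1, int(round(life_s / spec.frame_interval)))
        if n_live <= n_frames - 2:
            start = int(rng.integers(1, n_frames - 1 - n_live + 1))
            end = start + n_live - 1
            censored = False
        else:
            start = int(rng.integers(1, max(2, n_frames // 2)))
            end = n_frames - 1
            censored = True
        arr[i, start : end + 1] += spec.particle_intensity
        truth.append(
            LifetimeRecord(
                duration=(end - start + 1) * spec.frame_interval,
                censored=censored,
                start_frame=start,
                end_frame=end,
                row=i,
            )
        )
    if spec.noise_sd > 0:
        arr = arr + rng.normal(0.0, spec.noise_sd, size=arr.shape)
    return (
        Kymograph(array=arr, frame_interval=spec.frame_interval, pixel_size=spec.pixel_size),
        truth,
    )


# ---------------------------------------------------------------------------
# asymmetric root fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AsymmetryFieldSpec:
    """Two parallel horizontal bands with an imposed lower/upper fold.

    The upper band has noise-free mean ``upper_level``; the lower band
    ``lower_fold × upper_level``.  The returned truth is the imposed
    fold (the lower/upper ratio).
    """

    image_shape: tuple[int, int] = (200, 400)
    pixel_size: float = 0.2  # µm/pixel
    upper_level: float = 500.0  # AU
    lower_fold: float = 1.5
    band_width: int = 30  # px
    background: float = 20.0  # AU
    noise_sd: float = 0.0  # AU
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lower_fold > 0:
            raise ValueError("lower_fold must be > 0")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        h = self.image_shape[0]
        if 2 * self.band_width >= h:
            raise ValueError("bands do not fit in the image")

    @property
    def upper_rows(self) -> tuple[int, int]:
        h = self.image_shape[0]
        c = h // 4
        return (c - self.band_width // 2, c - self.band_width // 2 + self.band_width)

    @property
    def lower_rows(self) -> tuple[int, int]:
        h = self.image_shape[0]
        c = 3 * h // 4
        return (c - self.band_width // 2, c - self.band_width // 2 + self.band_width)


def generate_asymmetric_root(
    spec: AsymmetryFieldSpec,
) -> tuple[CalibratedImage, float]:
    """Render the two-band field; returns (image, true lower/upper ratio)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    img = np.full((h, w), float(spec.background))
    u0, u1 = spec.upper_rows
    l0, l1 = spec.lower_rows
    img[u0:u1, :] = spec.upper_level
    img[l0:l1, :] = spec.lower_fold * spec.upper_level
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    return CalibratedImage(img, spec.pixel_size), float(spec.lower_fold)


# ---------------------------------------------------------------------------
# spec serialisation
# ---------------------------------------------------------------------------

def spec_to_dict(spec) -> dict:
    """Plain-dict form of any generator spec (for the JSON run record)."""
    d = dataclasses.asdict(spec)
    d["spec_type"] = type(spec).__name__
    return d
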