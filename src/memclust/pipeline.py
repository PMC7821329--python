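"""Reproducible multi-stage pipeline with a run manifest.

A run is a YAML (or dict) config naming an ordered list of stages plus a
seed and output directory.  Every random draw flows from the config
seed; deterministic stages rerun bit-identically from the manifest
alone.  Each stage writes its tables/JSON into the output directory and
records the files it produced; a failing stage aborts the run with the
stage named, leaving earlier outputs in place next to a failure marker.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import asymmetry as _asym
from . import clusters as _clusters
from . import io as _io
from . import kinetics as _kin
from . import spt as _spt
from . import synthetic as _syn

__all__ = ["RunConfig", "RunManifest", "PipelineStageError", "run_pipeline"]

logger = logging.getLogger(__name__)

_KNOWN_STAGES = (
    "simulate_clusters",
    "simulate_tracks",
    "simulate_frap",
    "simulate_kymo",
    "simulate_root",
    "clusters",
    "outside_confidence",
    "spt",
    "frap",
    "lifetime",
    "asym",
)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``stages`` is an ordered list of dicts, each with a ``stage`` key
    naming one of the known stages plus stage-specific parameters.
    Tunables default to the package-wide defaults of their module.
    """

    stages: list[dict]
    out_dir: str
    seed: int = 0
    pixel_size: float | None = None  # µm/px fallback for image inputs
    frame_interval: float | None = None  # s fallback for stacks

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("config must list at least one stage")
        for i, st in enumerate(self.stages):
            if not isinstance(st, dict) or "stage" not in st:
                raise ValueError(f"stages[{i}] must be a mapping with a 'stage' key")
            if st["stage"] not in _KNOWN_STAGES:
                raise ValueError(
                    f"stages[{i}]: unknown stage {st['stage']!r}; "
                    f"known: {', '.join(_KNOWN_STAGES)}"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    seed: int
    package_version: str
    started: str
    finished: str = ""
    input_checksums: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(base_seed: int, index: int) -> int:
    # independent, reproducible per-stage streams
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % (2**31))


# --------------------------------------------------------------------------
# stage implementations: each takes (params, ctx) and returns output paths
# --------------------------------------------------------------------------

def _simulate_clusters(p: dict, ctx: dict) -> list[Path]:
    spec = _syn.ClusterFieldSpec(seed=ctx["seed"], **p)
    img, truth = _syn.generate_cluster_image(spec)
    out = ctx["out_dir"]
    _io.save_image(img, out / "cluster_field.tif")
    _io.clusters_to_csv(truth, out / "cluster_truth.csv")
    _io.write_json(_syn.spec_to_dict(spec), out / "cluster_spec.json")
    ctx["image"] = img
    ctx["cluster_truth"] = truth
    return [out / "cluster_field.tif", out / "cluster_truth.csv", out / "cluster_spec.json"]


def _simulate_tracks(p: dict, ctx: dict) -> list[Path]:
    render = p.pop("render", False)
    spec = _syn.TrajectoryFieldSpec(seed=ctx["seed"], **p)
    tracks = _syn.generate_trajectories(spec)
    out = ctx["out_dir"]
    _io.tracks_to_csv(tracks, out / "tracks_truth.csv")
    _io.write_json(_syn.spec_to_dict(spec), out / "tracks_spec.json")
    paths = [out / "tracks_truth.csv", out / "tracks_spec.json"]
    ctx["tracks"] = tracks
    if render:
        stack = _syn.render_trajectory_stack(spec, tracks)
        _io.save_image(stack, out / "tracks_movie.tif")
        ctx["stack"] = stack
        paths.append(out / "tracks_movie.tif")
    return paths


def _simulate_frap(p: dict, ctx: dict) -> list[Path]:
    spec = _syn.FRAPSpec(seed=ctx["seed"], **p)
    curve = _syn.generate_frap_curve(spec)
    out = ctx["out_dir"]
    import pandas as pd

    pd.DataFrame(
        {
            "t_s": curve.times,
            "intensity_AU": curve.intensity,
            "prebleach_AU": curve.prebleach_level,
            "background_AU": curve.background,
        }
    ).to_csv(out / "frap_curve.csv", index=False)
    _io.write_json(_syn.spec_to_dict(spec), out / "frap_spec.json")
    ctx["frap_curve"] = curve
    return [out / "frap_curve.csv", out / "frap_spec.json"]


def _simulate_kymo(p: dict, ctx: dict) -> list[Path]:
    spec = _syn.KymographSpec(seed=ctx["seed"], **p)
    kymo, truth = _syn.generate_kymograph(spec)
    out = ctx["out_dir"]
    _io.save_image(kymo, out / "kymograph.tif")
    _io.lifetimes_to_csv(truth, out / "lifetime_truth.csv")
    _io.write_json(_syn.spec_to_dict(spec), out / "kymo_spec.json")
    ctx["kymo"] = kymo
    ctx["kymo_spec"] = spec
    return [out / "kymograph.tif", out / "lifetime_truth.csv", out / "kymo_spec.json"]


def _simulate_root(p: dict, ctx: dict) -> list[Path]:
    spec = _syn.AsymmetryFieldSpec(seed=ctx["seed"], **p)
    img, true_ratio = _syn.generate_asymmetric_root(spec)
    out = ctx["out_dir"]
    _io.save_image(img, out / "root_field.tif")
    _io.write_json(
        {**_syn.spec_to_dict(spec), "true_ratio_lower_upper": true_ratio},
        out / "root_spec.json",
    )
    ctx["root_image"] = img
    ctx["root_spec"] = spec
    return [out / "root_field.tif", out / "root_spec.json"]


def _clusters_stage(p: dict, ctx: dict) -> list[Path]:
    img = ctx.get("image")
    if img is None:
        img = _io.load_image(p["image"], pixel_size=p.get("pixel_size", ctx["pixel_size"]))
    method = p.get("method", "otsu")
    mask = _clusters.segment_membrane(img, method=method)
    records = _clusters.detect_clusters(img, mask)
    dist = _clusters.size_distribution(records)
    out = ctx["out_dir"]
    _io.clusters_to_csv(records, out / "clusters.csv")
    summary = {
        "n_clusters": dist.n_total,
        "counts": dist.counts,
        "frequencies": dist.frequencies,
        "segmentation_method": method,
    }
    if len(records) >= 2:
        summary["mean_nn_spacing_um"] = _clusters.cluster_spacing(records).mean
    membrane = img.pixels[mask]
    if membrane.size >= 2 and membrane.mean() > 0:
        summary["clustering_index"] = _clusters.clustering_index(membrane).index
    _io.write_json(summary, out / "clusters_summary.json")
    ctx["membrane_intensities"] = membrane
    return [out / "clusters.csv", out / "clusters_summary.json"]


def _outside_confidence_stage(p: dict, ctx: dict) -> list[Path]:
    import pandas as pd

    if "treated_csv" in p:
        treated = pd.read_csv(p["treated_csv"]).iloc[:, 0].to_numpy()
        mock = pd.read_csv(p["mock_csv"]).iloc[:, 0].to_numpy()
    else:
        # null self-comparison on the membrane pixels of this run
        v = ctx["membrane_intensities"]
        rng = np.random.default_rng(ctx["seed"])
        idx = rng.permutation(v.size)
        mock, treated = v[idx[: v.size // 2]], v[idx[v.size // 2 :]]
    res = _clusters.outside_confidence(treated, mock, level=p.get("level", 95.0))
    out = ctx["out_dir"]
    _io.write_json(
        {
            "outside_confidence_percent": res.percentage,
            "interval_AU": list(res.interval),
            "n_mock": res.n_mock,
            "n_treated": res.n_treated,
        },
        out / "outside_confidence.json",
    )
    return [out / "outside_confidence.json"]


def _spt_stage(p: dict, ctx: dict) -> list[Path]:
    tracks = ctx.get("tracks")
    out = ctx["out_dir"]
    if tracks is None:
        stack = ctx.get("stack")
        if stack is None:
            stack = _io.load_image(
                p["stack"],
                pixel_size=p.get("pixel_size", ctx["pixel_size"]),
                frame_interval=p.get("frame_interval", ctx["frame_interval"]),
            )
        dets = [
            _spt.detect_spots(fr, expected_radius=p.get("expected_radius", 0.2))
            for fr in stack
        ]
        tracks = _spt.link_trajectories(
            dets,
            max_disp=p.get("max_disp", 0.5),
            max_gap=p.get("max_gap", 0),
            frame_interval=stack.frame_interval,
        )
        _io.tracks_to_csv(tracks, out / "tracks.csv")
    curve = _spt.compute_msd(tracks, min_length=p.get("min_length", 5))
    est = _spt.fit_diffusion(curve, n_fit_lags=p.get("n_fit_lags", 4))
    _io.msd_to_csv(curve, out / "msd.csv")
    _io.write_json(
        {
            "D_um2_per_s": est.D,
            "intercept_um2": est.intercept,
            "r_squared": est.r_squared,
            "fit_lags_s": list(est.fit_lags),
            "n_tracks": len(tracks),
        },
        out / "diffusion.json",
    )
    return [out / "msd.csv", out / "diffusion.json"]


def _frap_stage(p: dict, ctx: dict) -> list[Path]:
    curve = ctx.get("frap_curve")
    if curve is None:
        curve = _io.load_frap_csv(p["curve"])
    fit = _kin.fit_frap(_kin.normalize_frap(curve))
    out = ctx["out_dir"]
    _io.write_json(
        {
            "mobile_fraction": fit.mobile_fraction,
            "stable_fraction": fit.stable_fraction,
            "rate_k_per_s": fit.rate_k,
            "residual_rms": fit.residual_rms,
        },
        out / "frap_fit.json",
    )
    return [out / "frap_fit.json"]


def _lifetime_stage(p: dict, ctx: dict) -> list[Path]:
    kymo = ctx.get("kymo")
    if kymo is None:
        import tifffile

        arr = tifffile.imread(p["kymo"])
        kymo = _kin.Kymograph(
            array=np.asarray(arr, dtype=float),
            frame_interval=p.get("frame_interval", ctx["frame_interval"] or 1.0),
            pixel_size=p.get("pixel_size", ctx["pixel_size"] or 1.0),
        )
    thr = p.get("threshold")
    if thr is None:
        spec = ctx.get("kymo_spec")
        if spec is not None:
            thr = spec.background + 0.5 * spec.particle_intensity
        else:
            raise ValueError("lifetime stage needs an intensity threshold")
    records = _kin.measure_lifetimes(kymo, intensity_threshold=thr,
                                     min_frames=p.get("min_frames", 1))
    summary = _kin.summarize_lifetimes(records)
    out = ctx["out_dir"]
    _io.lifetimes_to_csv(records, out / "lifetimes.csv")
    _io.write_json(
        {
            "mean_lifetime_s": summary.mean,
            "median_lifetime_s": summary.median,
            "n_uncensored": summary.n,
            "n_censored": summary.n_censored,
            "threshold_AU": thr,
        },
        out / "lifetimes_summary.json",
    )
    return [out / "lifetimes.csv", out / "lifetimes_summary.json"]


def _asym_stage(p: dict, ctx: dict) -> list[Path]:
    img = ctx.get("root_image")
    if img is None:
        img = _io.load_image(p["image"], pixel_size=p.get("pixel_size", ctx["pixel_size"]))
    spec = ctx.get("root_spec")
    if "upper_rows" in p:
        u0, u1 = p["upper_rows"]
        l0, l1 = p["lower_rows"]
    elif spec is not None:
        u0, u1 = spec.upper_rows
        l0, l1 = spec.lower_rows
    else:
        raise ValueError("asym stage needs upper_rows/lower_rows")
    upper = np.zeros(img.shape, dtype=bool)
    upper[u0:u1, :] = True
    lower = np.zeros(img.shape, dtype=bool)
    lower[l0:l1, :] = True
    mu = _asym.region_intensity(img, upper, label="upper").mean
    ml = _asym.region_intensity(img, lower, label="lower").mean
    if mu <= 0:
        raise ValueError("upper-side mean is zero")
    out = ctx["out_dir"]
    _io.write_json(
        {"ratio_lower_upper": ml / mu, "mean_upper_AU": mu, "mean_lower_AU": ml},
        out / "asymmetry.json",
    )
    return [out / "asymmetry.json"]


_STAGE_FUNCS = {
    "simulate_clusters": _simulate_clusters,
    "simulate_tracks": _simulate_tracks,
    "simulate_frap": _simulate_frap,
    "simulate_kymo": _simulate_kymo,
    "simulate_root": _simulate_root,
    "clusters": _clusters_stage,
    "outside_confidence": _outside_confidence_stage,
    "spt": _spt_stage,
    "frap": _frap_stage,
    "lifetime": _lifetime_stage,
    "asym": _asym_stage,
}


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages in order and write the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        seed=config.seed,
        package_version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    ctx: dict = {
        "out_dir": out_dir,
        "pixel_size": config.pixel_size,
        "frame_interval": config.frame_interval,
    }
    for i, stage_cfg in enumerate(config.stages):
        params = {k: v for k, v in stage_cfg.items() if k != "stage"}
        name = stage_cfg["stage"]
        ctx["seed"] = _stage_seed(config.seed, i)
        for key in ("image", "stack", "kymo", "curve", "treated_csv", "mock_csv"):
            if key in params and isinstance(params[key], str):
                path = Path(params[key])
                if path.exists():
                    manifest.input_checksums[str(path)] = _sha256(path)
        logger.info("running stage %d: %s", i, name)
        try:
            produced = _STAGE_FUNCS[name](dict(params), ctx)
        except Exception as exc:
            (out_dir / "FAILED").write_text(f"stage {name}: {exc}\n")
            manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
            manifest.write(out_dir / "manifest.json")
            raise PipelineStageError(name, exc) from exc
        manifest.outputs.extend(str(p) for p in produced)
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out_dir / "manifest.json")
    return manifest
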