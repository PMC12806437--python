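"""End-to-end experiment runner: simulate -> extract -> preprocess -> train
-> render -> evaluate, with a manifest recording every artifact.

Configurations are YAML files whose sections mirror the library dataclasses;
unknown keys are rejected.  Every stage writes its outputs under the run
directory and appends SHA-256 hashes to ``manifest.json``, so re-running a
deterministic configuration reproduces identical manifests.
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .acquisition import AcquisitionSchedule, extract_strt_from_tomoscopy
from .data import ProjectionSet, Volume4D
from .forward import Geometry
from .phantom import PhantomSpec, make_phantom, simulate_tomoscopy
from .preprocess import radon_sum_normalize
from .scene import SceneConfig, SceneModel, init_scene
from .training import TrainConfig, fit, reconstruct_series
from .evaluate import fbp_reconstruct, fsc, metric_series

ALL_STAGES = ("simulate", "extract", "preprocess", "train", "render", "evaluate")


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Section):
    kind: str = "merging_droplets"
    grid_n: int = 32
    n_timepoints: int = 8
    delta_value: float = 1.0
    beta_value: float = 0.0


class AcquisitionSection(_Section):
    frames_per_rotation: int = 80
    rotations: int = 1
    n_frames: int | None = None
    noise: str = "none"
    noise_level: float = 0.0


class ScheduleSection(_Section):
    n_timepoints: int = 8
    wedge_deg: float = 18.0
    start_angle_deg: float = 0.0
    mode: str = "streaming"


class SceneSection(_Section):
    spatial_grid: int = 32
    temporal_grid: int = 16
    feature_dim: int = 8
    mlp_layers: int = 2
    mlp_width: int = 32
    out_channels: int = 1
    fusion_mode: str = "concat"
    output_activation: str = "softplus"


class TrainSection(_Section):
    epochs: int = 5000
    rays_per_batch: int = 512
    n_samples_per_ray: int | None = None
    lr_planes: float = 2e-2
    lr_mlp: float = 1e-3
    lambda_reg: float = 1e-4
    tv_weight_split: float = 0.5
    log_every: int = 100


class EvaluateSection(_Section):
    fbp_baseline: bool = True


class RunConfig(_Section):
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    stages: list[str] = list(ALL_STAGES)
    seed: int = 0
    phantom: PhantomSection = PhantomSection()
    acquisition: AcquisitionSection = AcquisitionSection()
    schedule: ScheduleSection = ScheduleSection()
    scene: SceneSection = SceneSection()
    train: TrainSection = TrainSection()
    evaluate: EvaluateSection = EvaluateSection()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage={stage} reason={cause}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute the requested stages in order, writing every intermediate.

    Returns the run directory; ``manifest.json`` lists each stage's output
    files with SHA-256 hashes, the configuration, the seed and the package
    version.  A stage failure aborts with the stage name; artifacts of
    completed stages persist.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(config.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.model_dump(),
        "stages": {},
    }
    state: dict = {}

    def record(stage: str, paths: list[Path]) -> None:
        manifest["stages"][stage] = [
            {"file": p.name, "sha256": _sha256(p)} for p in paths
        ]
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    for stage in config.stages:
        try:
            paths = _run_stage(stage, config, out, state)
        except Exception as exc:  # noqa: BLE001 - abort names the stage
            raise StageError(stage, exc) from exc
        record(stage, paths)
    return out


def _load_projections(out: Path, state: dict, *names: str) -> ProjectionSet:
    for name in names:
        if name in state:
            return state[name]
        p = out / f"{name}.h5"
        if p.exists():
            return ProjectionSet.from_hdf5(p)
    raise FileNotFoundError(f"none of {names} available; run earlier stages first")


def _run_stage(stage: str, cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    if stage == "simulate":
        spec = PhantomSpec(seed=cfg.seed, **cfg.phantom.model_dump())
        phantom = make_phantom(spec)
        acq = cfg.acquisition
        stack = simulate_tomoscopy(
            phantom,
            frames_per_rotation=acq.frames_per_rotation,
            rotations=acq.rotations,
            n_frames=acq.n_frames,
            noise=acq.noise,
            noise_level=acq.noise_level,
            seed=cfg.seed,
        )
        phantom.to_hdf5(out / "phantom.h5")
        stack.to_hdf5(out / "tomoscopy.h5")
        state["phantom"], state["tomoscopy"] = phantom, stack
        return [out / "phantom.h5", out / "tomoscopy.h5"]

    if stage == "extract":
        stack = _load_projections(out, state, "tomoscopy")
        sched = AcquisitionSchedule(
            n_timepoints=cfg.schedule.n_timepoints,
            wedge_deg=cfg.schedule.wedge_deg,
            frames_per_rotation=cfg.acquisition.frames_per_rotation,
            start_angle_deg=cfg.schedule.start_angle_deg,
        )
        strt = extract_strt_from_tomoscopy(stack, sched, mode=cfg.schedule.mode)
        with open(out / "schedule.json", "w") as fh:
            json.dump(sched.to_dict(), fh, indent=2)
        strt.to_hdf5(out / "strt.h5")
        state["strt"] = strt
        return [out / "schedule.json", out / "strt.h5"]

    if stage == "preprocess":
        strt = _load_projections(out, state, "strt", "tomoscopy")
        normed, factors = radon_sum_normalize(strt)
        normed.to_hdf5(out / "preprocessed.h5")
        np.savetxt(out / "radon_scale_factors.csv", factors, delimiter=",")
        state["preprocessed"] = normed
        return [out / "preprocessed.h5", out / "radon_scale_factors.csv"]

    if stage == "train":
        data = _load_projections(out, state, "preprocessed", "strt", "tomoscopy")
        geom = Geometry(
            detector_rows=data.detector_shape[0],
            detector_cols=data.detector_shape[1],
            pixel_size=data.pixel_size,
        )
        scene = init_scene(SceneConfig(seed=cfg.seed, **cfg.scene.model_dump()))
        tcfg = TrainConfig(seed=cfg.seed, **cfg.train.model_dump())
        scene, history = fit(scene, data, geom, tcfg)
        scene.save(out / "scene.h5")
        with open(out / "history.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            # wall time is kept in memory only so the file is run-reproducible
            w.writerow(["iteration", "data_loss", "reg_value", "total_loss"])
            w.writerows(r[:4] for r in history.to_rows())
        state["scene"] = scene
        return [out / "scene.h5", out / "history.csv"]

    if stage == "render":
        scene = state.get("scene") or SceneModel.load(out / "scene.h5")
        recon = reconstruct_series(
            scene, cfg.phantom.grid_n, cfg.schedule.n_timepoints
        )
        recon.to_hdf5(out / "recon.h5")
        state["recon"] = recon
        return [out / "recon.h5"]

    if stage == "evaluate":
        phantom = state.get("phantom") or Volume4D.from_hdf5(out / "phantom.h5")
        recon = state.get("recon") or Volume4D.from_hdf5(out / "recon.h5")
        metrics = metric_series(recon, phantom)
        rows = {
            k: metrics[k]
            for k in ("fsc_resolution", "psnr", "ssim", "nrmse")
        }
        if cfg.evaluate.fbp_baseline and ("strt" in state or (out / "strt.h5").exists()):
            strt = _load_projections(out, state, "strt")
            res = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for i in range(phantom.n_timepoints):
                    wedge = strt.select(strt.time_index == i)
                    vol = fbp_reconstruct(wedge, output_size=cfg.phantom.grid_n)
                    res.append(fsc(vol, phantom.delta[i]).resolution_voxels)
            rows["fbp_fsc_resolution"] = np.asarray(res)
        with open(out / "metrics.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            keys = list(rows)
            w.writerow(["time_index"] + keys)
            for i in range(phantom.n_timepoints):
                w.writerow([i] + [f"{rows[k][i]:.6f}" for k in keys])
        summary = {
            k: metrics[k]
            for k in metrics
            if isinstance(metrics[k], float)
        }
        with open(out / "metrics.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return [out / "metrics.csv", out / "metrics.json"]

    raise ValueError(f"unknown stage {stage!r}")
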