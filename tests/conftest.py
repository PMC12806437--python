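"""Shared fixtures: small deterministic scenes, phantoms, and the two
expensive end-to-end fits (static self-consistency and dynamic wedge
recovery) reused by several acceptance checks."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from strtomo.acquisition import build_schedule, extract_strt_from_tomoscopy
from strtomo.forward import Geometry
from strtomo.phantom import PhantomSpec, make_phantom, reference_descriptors, simulate_tomoscopy
from strtomo.scene import SceneConfig, init_scene
from strtomo.training import TrainConfig, fit, reconstruct_series
from strtomo.evaluate import fbp_reconstruct, fsc


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_scene():
    """A small two-channel scene for exactness/oracle tests."""
    cfg = SceneConfig(
        spatial_grid=5,
        temporal_grid=4,
        feature_dim=3,
        mlp_layers=2,
        mlp_width=6,
        out_channels=2,
        seed=11,
    )
    return init_scene(cfg)


@pytest.fixture
def ball_phantom():
    return make_phantom(PhantomSpec(kind="static_ball", grid_n=32, n_timepoints=1))


@pytest.fixture
def geom32():
    return Geometry.for_cube(32)


@pytest.fixture(scope="session")
def static_fit():
    """Fit a small scene to noiseless 90-angle projections of a static ball.

    Shared by the self-consistency checks: scene planes at 32, F=8,
    MLP 2x32, 3000 optimizer steps.
    """
    phantom = make_phantom(PhantomSpec(kind="static_ball", grid_n=32, n_timepoints=1))
    geom = Geometry.for_cube(32)
    proj = simulate_tomoscopy(phantom, frames_per_rotation=180, n_frames=90, seed=0)
    scene = init_scene(
        SceneConfig(spatial_grid=32, temporal_grid=8, feature_dim=8,
                    mlp_layers=2, mlp_width=32, out_channels=1, seed=0)
    )
    scene, history = fit(
        scene, proj, geom,
        TrainConfig(epochs=3000, rays_per_batch=512, seed=0, log_every=500),
    )
    return {"phantom": phantom, "geom": geom, "proj": proj,
            "scene": scene, "history": history}


@pytest.fixture(scope="session")
def droplet_recovery():
    """Dynamic wedge-recovery experiment: 8 time points, 18-degree wedges.

    A merging-droplet phantom at 32^3 is virtually acquired over 32
    consecutive frames (80 frames/rotation, so 4 frames per wedge, 144
    degrees total coverage), carved into an STRT set in streaming mode, and
    fitted for 5000 steps.  The per-time single-wedge filtered-back-
    projection baseline is reconstructed from each wedge's own frames.
    """
    phantom = make_phantom(
        PhantomSpec(kind="merging_droplets", grid_n=32, n_timepoints=8)
    )
    geom = Geometry.for_cube(32)
    stack = simulate_tomoscopy(phantom, frames_per_rotation=80, n_frames=32, seed=0)
    sched = build_schedule(n_timepoints=8, wedge_deg=18.0, frames_per_rotation=80)
    strt = extract_strt_from_tomoscopy(stack, sched, mode="streaming")
    scene = init_scene(
        SceneConfig(spatial_grid=32, temporal_grid=16, feature_dim=8,
                    mlp_layers=2, mlp_width=32, out_channels=1, seed=0)
    )
    scene, history = fit(
        scene, strt, geom,
        TrainConfig(epochs=5000, rays_per_batch=512, seed=0, log_every=1000),
    )
    recon = reconstruct_series(scene, 32, phantom.times)
    res_strt, res_fbp = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(phantom.n_timepoints):
            res_strt.append(fsc(recon.delta[i], phantom.delta[i]).resolution_voxels)
            wedge = strt.select(strt.time_index == i)
            vol = fbp_reconstruct(wedge)
            res_fbp.append(fsc(vol, phantom.delta[i]).resolution_voxels)
    return {
        "phantom": phantom,
        "reference": reference_descriptors(phantom),
        "strt": strt,
        "scene": scene,
        "recon": recon,
        "res_strt": np.asarray(res_strt),
        "res_fbp": np.asarray(res_fbp),
    }
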