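"""Self-supervised fitting of the scene to measured radiographs.

The scene is optimized by minimizing, over random ray batches drawn from the
measured frames, the mean squared error between rendered and measured
line-integral pixels plus a weighted total-variation + L1 penalty on the six
feature planes:

    L = (1/|R|) sum_{r in R} || I(r) - I_hat(r) ||^2  +  lambda_reg * L_reg

The regularizer enforces spatial-temporal smoothness and sparsity of the
plane features, which is what stabilizes the severely limited-angle inverse
problem.  One "epoch" here is one optimizer step on one random ray batch
(iteration counts in the tens of thousands correspond to minutes of
fitting at full scale).

Optimization uses Adam with separate learning rates for the planes and the
MLP and cosine learning-rate decay; gradients are computed analytically by
the scene's backward pass.  The whole loop is deterministic given the
config seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .data import ProjectionSet, Volume4D, normalized_times
from .forward import Geometry, generate_rays, sample_along_ray
from .scene import SceneModel, backward_points, evaluate_field, forward_points


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    """Hyperparameters of one fitting run.

    ``epochs`` counts optimizer steps (one random ray batch each);
    ``lambda_reg`` weights the plane regularizer and ``tv_weight_split``
    divides it between the TV term (weight = split) and the L1 term
    (weight = 1 - split).
    """

    epochs: int = 5000
    rays_per_batch: int = 1024
    n_samples_per_ray: int | None = None
    lr_planes: float = 2e-2
    lr_mlp: float = 1e-3
    lambda_reg: float = 1e-4
    tv_weight_split: float = 0.5
    seed: int = 0
    cosine_decay: bool = True
    stratified: bool = True
    log_every: int = 100

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.rays_per_batch < 1:
            raise ValueError("rays_per_batch must be >= 1")
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if not 0.0 <= self.tv_weight_split <= 1.0:
            raise ValueError("tv_weight_split must be in [0, 1]")


@dataclass
class TrainHistory:
    """Per-logging-step record: iteration, loss components, wall time."""

    iteration: list = field(default_factory=list)
    data_loss: list = field(default_factory=list)
    reg_value: list = field(default_factory=list)
    total_loss: list = field(default_factory=list)
    wall_time: list = field(default_factory=list)

    def log(self, it, data, reg, total, t):
        self.iteration.append(int(it))
        self.data_loss.append(float(data))
        self.reg_value.append(float(reg))
        self.total_loss.append(float(total))
        self.wall_time.append(float(t))

    def to_rows(self):
        return list(zip(self.iteration, self.data_loss, self.reg_value,
                        self.total_loss, self.wall_time))


# ------------------------------------------------------------- regularizer


def plane_regularizer(planes, tv_weight_split: float = 0.5) -> float:
    """Weighted TV + L1 penalty on the feature planes.

    TV is the mean over the six planes of the per-plane mean of squared
    forward differences along both plane axes (all channels); L1 is the
    mean over planes of the per-plane mean absolute feature value.
    """
    tv, l1 = _reg_terms(planes)
    return tv_weight_split * tv + (1.0 - tv_weight_split) * l1


def _reg_terms(planes):
    tv_vals, l1_vals = [], []
    for p in planes:
        d0 = np.diff(p, axis=0)
        d1 = np.diff(p, axis=1)
        n_diff = d0.size + d1.size
        tv_vals.append(((d0**2).sum() + (d1**2).sum()) / n_diff)
        l1_vals.append(np.abs(p).mean())
    return float(np.mean(tv_vals)), float(np.mean(l1_vals))


def _reg_grads(planes, tv_weight_split: float):
    """Analytic gradient of :func:`plane_regularizer` w.r.t. each plane."""
    w_tv = tv_weight_split / len(planes)
    w_l1 = (1.0 - tv_weight_split) / len(planes)
    grads = []
    for p in planes:
        g = np.zeros_like(p)
        d0 = np.diff(p, axis=0)
        d1 = np.diff(p, axis=1)
        n_diff = d0.size + d1.size
        c = 2.0 * w_tv / n_diff
        g[1:] += c * d0
        g[:-1] -= c * d0
        g[:, 1:] += c * d1
        g[:, :-1] -= c * d1
        g += w_l1 * np.sign(p) / p.size
        grads.append(g)
    return grads


def strt_loss(
    pred: np.ndarray,
    target: np.ndarray,
    planes,
    lambda_reg: float,
    tv_weight_split: float = 0.5,
):
    """Total loss and its components for a rendered/measured pixel batch.

    Returns ``(total, data, reg)`` with data = mean squared pixel
    difference over the batch and total = data + lambda_reg * reg.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError("pred and target shapes differ")
    data = float(np.mean((pred - target) ** 2))
    reg = plane_regularizer(planes, tv_weight_split)
    return data + lambda_reg * reg, data, reg


# -------------------------------------------------------------------- Adam


class _Adam:
    def __init__(self, params, lrs, beta1=0.9, beta2=0.99, eps=1e-8):
        self.lrs = lrs
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads, lr_scale=1.0):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, g, m, v, lr in zip(params, grads, self.m, self.v, self.lrs):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= (lr * lr_scale) * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# --------------------------------------------------------------------- fit


def fit(
    scene: SceneModel,
    projections: ProjectionSet,
    geom: Geometry,
    config: TrainConfig,
) -> tuple[SceneModel, TrainHistory]:
    """Fit the scene to a projection set by stochastic ray batches.

    Each step draws one frame uniformly at random, samples
    ``rays_per_batch`` detector pixels without replacement within it,
    renders their line integrals by stratified quadrature, and applies one
    Adam update of the MSE + regularizer loss.  Deterministic given
    ``config.seed``.  Aborts with a diagnostic naming the iteration if the
    loss turns non-finite.

    When the scene has two output channels and the projections are
    attenuation-domain (``beta_line_integral``) the beta channel is
    supervised; otherwise the delta channel is.  With two channels and a
    delta-domain target only the delta channel receives data gradients (the
    beta channel is then constrained by the regularizer alone).
    """
    config.validate()
    n_samples = config.n_samples_per_ray
    if n_samples is None:
        n_samples = max(scene.config.spatial_grid, scene.config.temporal_grid)
    rng = np.random.default_rng(config.seed)
    channel = 1 if (
        scene.config.out_channels == 2
        and projections.contrast_domain == "beta_line_integral"
    ) else 0

    # per-unique-angle ray cache (parallel rays depend only on theta mod 360)
    theta_mod = np.round(projections.theta_mod(), 9)
    unique_thetas, theta_inv = np.unique(theta_mod, return_inverse=True)
    ray_cache = [generate_rays(geom, th) for th in unique_thetas]

    params = scene.parameters()
    n_planes = len(scene.planes)
    opt = _Adam(
        params,
        lrs=[config.lr_planes] * n_planes
        + [config.lr_mlp] * len(scene.weights),
    )
    history = TrainHistory()
    t0 = time.perf_counter()
    n_frames = projections.n_frames
    n_pix = geom.n_pixels
    batch = min(config.rays_per_batch, n_pix)

    for it in range(config.epochs):
        f = int(rng.integers(n_frames))
        pix = rng.choice(n_pix, size=batch, replace=False)
        rays = ray_cache[theta_inv[f]]
        sub = type(rays)(
            origin=rays.origin[pix],
            direction=rays.direction[pix],
            t_far=rays.t_far[pix],
        )
        mode = "stratified" if config.stratified else "uniform"
        pos, w = sample_along_ray(sub, n_samples, mode=mode, seed=rng)
        pts = np.concatenate(
            [pos.reshape(-1, 3),
             np.full((batch * n_samples, 1), projections.t_norm[f])],
            axis=1,
        )
        out, cache = forward_points(scene, pts)
        vals = out[:, channel].reshape(batch, n_samples)
        pred = (w * vals).sum(axis=1)
        target = projections.frames[f].reshape(-1)[pix]

        resid = pred - target
        data = float(np.mean(resid**2))
        tv, l1 = _reg_terms(scene.planes)
        reg = config.tv_weight_split * tv + (1.0 - config.tv_weight_split) * l1
        total = data + config.lambda_reg * reg
        if not np.isfinite(total):
            raise TrainingError(f"non-finite loss at iteration {it}")

        d_pred = 2.0 * resid / batch
        d_out = np.zeros_like(out)
        d_out[:, channel] = (d_pred[:, None] * w).reshape(-1)
        grads = backward_points(scene, cache, d_out)
        if config.lambda_reg > 0:
            for g, rg in zip(grads[:n_planes],
                             _reg_grads(scene.planes, config.tv_weight_split)):
                g += config.lambda_reg * rg

        lr_scale = 1.0
        if config.cosine_decay and config.epochs > 1:
            lr_scale = 0.5 * (1.0 + np.cos(np.pi * it / (config.epochs - 1)))
            lr_scale = max(lr_scale, 0.01)
        opt.step(params, grads, lr_scale=lr_scale)

        if it % config.log_every == 0 or it == config.epochs - 1:
            history.log(it, data, reg, total, time.perf_counter() - t0)

    return scene, history


def reconstruct_series(
    scene: SceneModel,
    grid,
    times: np.ndarray | int,
) -> Volume4D:
    """Dense volumes at the requested normalized times, stacked over time.

    ``times`` may be an integer T (cell-centered normalized stamps) or an
    explicit array in [-1, 1]; stamps outside the training range are
    evaluated through plane edge-clamping and flagged in the metadata.
    """
    if np.isscalar(times):
        times = normalized_times(int(times))
    times = np.asarray(times, dtype=np.float64)
    if np.isscalar(grid):
        grid = (int(grid),) * 3
    fields = [evaluate_field(scene, grid, t) for t in times]
    arr = np.stack(fields)  # (T, nx, ny, nz, C)
    extrapolated = bool(np.any((times < -1.0) | (times > 1.0)))
    return Volume4D(
        delta=arr[..., 0],
        beta=arr[..., 1] if scene.config.out_channels == 2 else None,
        times=times,
        voxel_size=2.0 / grid[0],
        meta={"extrapolated": extrapolated},
    )
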