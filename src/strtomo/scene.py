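"""Six-plane tensorial scene representation of a dynamic refractive-index field.

A 4D field n(x, t) = 1 - delta + i*beta over the normalized spacetime cube
[-1, 1]^4 is factorized into six learnable 2D feature planes, one per pair of
coordinate axes: (x,y), (z,t), (x,z), (y,t), (y,z), (x,t).  The three purely
spatial planes carry structure shared across all times; the three
space-time planes modulate it along the time axis.  A query point is
projected onto each plane, the plane features are bilinearly interpolated,
fused (concatenation by default), and decoded by a small MLP into the
non-negative (delta, beta) pair.

Storing N x N (and N x T) planes of F channels instead of a dense N^3 T voxel
grid reduces the parameter count from O(N^3 T) to O(N^2 F + N T F), which is
what makes fitting the field directly to radiographs tractable.

All tensors are plain float64 numpy arrays; the analytic backward pass for
fitting lives in :func:`backward_points` and mirrors :func:`forward_points`
exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

#: plane names and the (x, y, z, t) axis pair each one spans
PLANE_NAMES = ("xy", "zt", "xz", "yt", "yz", "xt")
PLANE_AXES = ((0, 1), (2, 3), (0, 2), (1, 3), (1, 2), (0, 3))
#: complementary plane pairs used by multiplicative fusion:
#: (xy, zt), (xz, yt), (yz, xt) jointly cover all four axes
PAIRED_PLANES = ((0, 1), (2, 3), (4, 5))


class SceneConfigError(ValueError):
    """Raised when a scene configuration field is invalid."""


@dataclass
class SceneConfig:
    """Architecture hyperparameters of the six-plane scene.

    Parameters
    ----------
    spatial_grid : int
        Plane resolution along each spatial axis (X, Y, Z).
    temporal_grid : int
        Plane resolution along the time axis.
    feature_dim : int
        Channel count F of every plane (the shared low-rank component count).
    mlp_layers, mlp_width : int
        Number of hidden layers and neurons per layer of the decoder MLP.
    out_channels : int
        1 for a delta-only field (attenuation not modelled), 2 for
        (delta, beta).
    fusion_mode : str
        ``"concat"`` builds a 6F descriptor by concatenating all plane
        features; ``"paired-product"`` multiplies complementary planes
        elementwise first, giving a 3F descriptor.
    output_activation : str
        ``"softplus"`` (default) keeps delta and beta non-negative;
        ``"linear"`` returns the raw MLP output.
    seed : int
        Seed for parameter initialization.
    """

    spatial_grid: int = 64
    temporal_grid: int = 64
    feature_dim: int = 48
    mlp_layers: int = 3
    mlp_width: int = 64
    out_channels: int = 2
    fusion_mode: str = "concat"
    output_activation: str = "softplus"
    seed: int = 0

    def validate(self) -> None:
        if self.spatial_grid < 2:
            raise SceneConfigError("spatial_grid must be >= 2")
        if self.temporal_grid < 2:
            raise SceneConfigError("temporal_grid must be >= 2")
        if self.feature_dim < 1:
            raise SceneConfigError("feature_dim must be >= 1")
        if self.mlp_layers < 1:
            raise SceneConfigError("mlp_layers must be >= 1")
        if self.mlp_width < 1:
            raise SceneConfigError("mlp_width must be >= 1")
        if self.out_channels not in (1, 2):
            raise SceneConfigError("out_channels must be 1 or 2")
        if self.fusion_mode not in ("concat", "paired-product"):
            raise SceneConfigError("fusion_mode must be 'concat' or 'paired-product'")
        if self.output_activation not in ("softplus", "linear"):
            raise SceneConfigError("output_activation must be 'softplus' or 'linear'")

    @property
    def descriptor_dim(self) -> int:
        k = 6 if self.fusion_mode == "concat" else 3
        return k * self.feature_dim

    def plane_shape(self, plane_index: int) -> tuple[int, int, int]:
        ax = PLANE_AXES[plane_index]
        sizes = [self.spatial_grid] * 3 + [self.temporal_grid]
        return sizes[ax[0]], sizes[ax[1]], self.feature_dim


@dataclass
class RefractiveValue:
    """Decoded refractive-index components at one spacetime point."""

    delta: float
    beta: float | None = None


@dataclass
class SceneModel:
    """Learnable scene: six feature planes plus the decoder MLP.

    ``planes`` is a list of six (G1, G2, F) arrays ordered as
    :data:`PLANE_NAMES`; ``weights`` alternates MLP weight matrices and bias
    vectors, ending with the output layer.
    """

    config: SceneConfig
    planes: list = field(default_factory=list)
    weights: list = field(default_factory=list)

    def parameters(self) -> list:
        """All learnable arrays (planes first, then MLP), in a fixed order."""
        return list(self.planes) + list(self.weights)

    @property
    def n_plane_parameters(self) -> int:
        return sum(p.size for p in self.planes)

    @property
    def n_mlp_parameters(self) -> int:
        return sum(w.size for w in self.weights)

    @property
    def n_parameters(self) -> int:
        return self.n_plane_parameters + self.n_mlp_parameters

    # -------------------------------------------------------------- HDF5 I/O
    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            g = f.create_group("planes")
            for name, plane in zip(PLANE_NAMES, self.planes):
                g.create_dataset(name, data=plane, track_times=False)
            m = f.create_group("mlp")
            for i, w in enumerate(self.weights):
                m.create_dataset(f"p{i:02d}", data=w, track_times=False)
            f.attrs["config"] = json.dumps(asdict(self.config))

    @classmethod
    def load(cls, path) -> "SceneModel":
        with h5py.File(path, "r") as f:
            config = SceneConfig(**json.loads(f.attrs["config"]))
            planes = [f["planes"][name][()] for name in PLANE_NAMES]
            keys = sorted(f["mlp"].keys())
            weights = [f["mlp"][k][()] for k in keys]
        return cls(config=config, planes=planes, weights=weights)


def init_scene(config: SceneConfig) -> SceneModel:
    """Initialize a scene from its configuration, deterministically.

    Plane features are drawn uniform(-0.1, 0.1)/sqrt(F); MLP weights use
    uniform fan-in scaling.  Two calls with equal configs (same seed)
    produce bitwise-identical parameters.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    scale = 0.1 / np.sqrt(config.feature_dim)
    planes = [
        rng.uniform(-scale, scale, size=config.plane_shape(i)) for i in range(6)
    ]
    dims = [config.descriptor_dim] + [config.mlp_width] * config.mlp_layers
    weights: list[np.ndarray] = []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        bound = 1.0 / np.sqrt(d_in)
        weights.append(rng.uniform(-bound, bound, size=(d_in, d_out)))
        weights.append(rng.uniform(-bound, bound, size=(d_out,)))
    bound = 1.0 / np.sqrt(dims[-1])
    weights.append(rng.uniform(-bound, bound, size=(dims[-1], config.out_channels)))
    weights.append(rng.uniform(-bound, bound, size=(config.out_channels,)))
    return SceneModel(config=config, planes=planes, weights=weights)


# ---------------------------------------------------------------- forward


def _interp_coords(coord: np.ndarray, grid: int):
    """Map [-1, 1] coordinates to clamped bilinear corner indices/weights."""
    g = (np.clip(coord, -1.0, 1.0) + 1.0) * 0.5 * (grid - 1)
    i0 = np.clip(np.floor(g).astype(np.int64), 0, grid - 2)
    frac = g - i0
    return i0, frac


def _interp_plane(plane: np.ndarray, u: np.ndarray, v: np.ndarray):
    """Bilinear interpolation of a (G1, G2, F) plane at points (u, v).

    Returns the (P, F) features and the cache needed for the backward
    scatter.  Coordinates at the grid edges clamp, so interpolation at a
    node reproduces the stored feature exactly.
    """
    g1, g2, f = plane.shape
    i0, fu = _interp_coords(u, g1)
    j0, fv = _interp_coords(v, g2)
    w00 = (1 - fu) * (1 - fv)
    w01 = (1 - fu) * fv
    w10 = fu * (1 - fv)
    w11 = fu * fv
    flat = plane.reshape(g1 * g2, f)
    base = i0 * g2 + j0
    feat = (
        w00[:, None] * flat[base]
        + w01[:, None] * flat[base + 1]
        + w10[:, None] * flat[base + g2]
        + w11[:, None] * flat[base + g2 + 1]
    )
    cache = (base, (w00, w01, w10, w11), plane.shape)
    return feat, cache


def _scatter_plane_grad(cache, d_feat: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`_interp_plane`: accumulate gradients at corners."""
    base, (w00, w01, w10, w11), shape = cache
    g1, g2, f = shape
    offsets = (0, 1, g2, g2 + 1)
    idx = np.concatenate([(base + off) * f for off in offsets])
    ch = np.arange(f)
    w = np.concatenate(
        [(wk[:, None] * d_feat).ravel() for wk in (w00, w01, w10, w11)]
    )
    grad = np.bincount((idx[:, None] + ch).ravel(), weights=w,
                       minlength=g1 * g2 * f)
    return grad.reshape(shape)


def query_features(scene: SceneModel, points: np.ndarray) -> np.ndarray:
    """Fused feature descriptors at normalized spacetime points.

    Parameters
    ----------
    points : ndarray, shape (P, 4)
        Columns (x, y, z, t), each in [-1, 1].

    Returns
    -------
    ndarray, shape (P, D)
        D = 6F descriptors for ``concat`` fusion, 3F for ``paired-product``.
        An empty point list yields an empty (0, D) array.
    """
    desc, _ = _fuse_features(scene, np.asarray(points, dtype=np.float64))
    return desc


def _fuse_features(scene: SceneModel, points: np.ndarray):
    if points.ndim != 2 or points.shape[1] != 4:
        raise ValueError("points must have shape (P, 4)")
    feats = []
    caches = []
    for plane, (a, b) in zip(scene.planes, PLANE_AXES):
        f, c = _interp_plane(plane, points[:, a], points[:, b])
        feats.append(f)
        caches.append(c)
    if scene.config.fusion_mode == "concat":
        desc = np.concatenate(feats, axis=1)
    else:  # paired-product
        desc = np.concatenate([feats[i] * feats[j] for i, j in PAIRED_PLANES], axis=1)
    return desc, (caches, feats)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def decode(scene: SceneModel, descriptors: np.ndarray) -> np.ndarray:
    """Decode fused descriptors to (delta[, beta]) values via the MLP.

    Returns a (P, out_channels) array; deterministic given the scene
    parameters.
    """
    out, _ = _mlp_forward(scene, np.asarray(descriptors, dtype=np.float64))
    return out


def _mlp_forward(scene: SceneModel, desc: np.ndarray):
    cfg = scene.config
    if desc.ndim != 2 or desc.shape[1] != cfg.descriptor_dim:
        raise ValueError(
            f"descriptor width {desc.shape[-1] if desc.ndim == 2 else '?'} does not "
            f"match MLP input width {cfg.descriptor_dim}"
        )
    h = desc
    hidden = []
    ws = scene.weights
    for layer in range(cfg.mlp_layers):
        z = h @ ws[2 * layer] + ws[2 * layer + 1]
        h = np.maximum(z, 0.0)
        hidden.append((z, h))
    pre = h @ ws[-2] + ws[-1]
    if cfg.output_activation == "softplus":
        out = _softplus(pre)
    else:
        out = pre
    return out, (desc, hidden, pre)


def forward_points(scene: SceneModel, points: np.ndarray):
    """Full differentiable forward pass: points -> (values, cache)."""
    desc, fuse_cache = _fuse_features(scene, np.asarray(points, dtype=np.float64))
    out, mlp_cache = _mlp_forward(scene, desc)
    return out, (fuse_cache, mlp_cache)


def backward_points(scene: SceneModel, cache, d_out: np.ndarray):
    """Analytic gradients of sum(d_out * output) w.r.t. all parameters.

    Returns gradients in the order of :meth:`SceneModel.parameters`:
    six plane gradients followed by the MLP weight/bias gradients.
    """
    (caches, feats), (desc, hidden, pre) = cache
    cfg = scene.config
    ws = scene.weights
    if cfg.output_activation == "softplus":
        d_pre = d_out * _sigmoid(pre)
    else:
        d_pre = d_out
    grads_w = [None] * len(ws)
    h_last = hidden[-1][1] if hidden else desc
    grads_w[-2] = h_last.T @ d_pre
    grads_w[-1] = d_pre.sum(axis=0)
    d_h = d_pre @ ws[-2].T
    for layer in range(cfg.mlp_layers - 1, -1, -1):
        z, _ = hidden[layer]
        d_z = d_h * (z > 0)
        h_prev = hidden[layer - 1][1] if layer > 0 else desc
        grads_w[2 * layer] = h_prev.T @ d_z
        grads_w[2 * layer + 1] = d_z.sum(axis=0)
        d_h = d_z @ ws[2 * layer].T
    d_desc = d_h
    f = cfg.feature_dim
    if cfg.fusion_mode == "concat":
        d_feats = [d_desc[:, k * f:(k + 1) * f] for k in range(6)]
    else:
        d_feats = [None] * 6
        for k, (i, j) in enumerate(PAIRED_PLANES):
            d_pair = d_desc[:, k * f:(k + 1) * f]
            d_feats[i] = d_pair * feats[j]
            d_feats[j] = d_pair * feats[i]
    grads_p = [_scatter_plane_grad(c, df) for c, df in zip(caches, d_feats)]
    return grads_p + grads_w


def evaluate_field(scene: SceneModel, grid, t: float, chunk: int = 65536) -> np.ndarray:
    """Dense evaluation of the field at one normalized time.

    Parameters
    ----------
    grid : int or (nx, ny, nz)
        Voxel counts per axis; voxel centers are cell-centered in [-1, 1].
    t : float
        Normalized time in [-1, 1] (values outside clamp to the plane edge).

    Returns
    -------
    ndarray, shape (nx, ny, nz, out_channels)
    """
    if np.isscalar(grid):
        grid = (int(grid),) * 3
    nx, ny, nz = grid
    from .data import voxel_centers

    xs, ys, zs = (voxel_centers(n) for n in grid)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack(
        [gx.ravel(), gy.ravel(), gz.ravel(), np.full(gx.size, float(t))], axis=1
    )
    out = np.empty((pts.shape[0], scene.config.out_channels))
    for lo in range(0, pts.shape[0], chunk):
        sl = slice(lo, lo + chunk)
        out[sl] = decode(scene, query_features(scene, pts[sl]))
    return out.reshape(nx, ny, nz, scene.config.out_channels)
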