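"""Synthetic 4D ground-truth phantoms and virtual tomoscopy acquisition.

Three phantom families cover the dynamic regimes the reconstruction engine
is built for:

* ``merging_droplets`` — two spherical bodies approach, touch, and coalesce
  into a single relaxing blob (a morphological stand-in for binary droplet
  collision).  The implicit surface is a smooth-min of the two sphere
  distance fields, and the iso-level is re-solved at every time point so the
  occupied voxel volume is conserved through the merge.
* ``melt_pool`` — a static substrate slab plus a higher-contrast ellipsoidal
  molten region translating at constant velocity (additive-manufacturing
  regime: static background, localized dynamics).
* ``static_ball`` — a time-constant centered ball, the canonical
  self-consistency target.

Phantom delta values are exactly the configured contrast levels inside and
outside (piecewise-constant fields), so threshold segmentation of the ground
truth is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .data import ProjectionSet, Volume4D, voxel_centers, normalized_times
from .forward import Geometry, project_volume_oracle


class PhantomSpecError(ValueError):
    pass


@dataclass
class PhantomSpec:
    """Parameters of a synthetic 4D phantom.

    Lengths are in normalized volume units (the cube spans [-1, 1]).
    Droplet parameters: initial centers at +-``droplet_separation``/2 along
    x, radii ``droplet_radii``, smooth-min blend sharpness ``blend_k``;
    centers approach linearly over the sequence and the merged blob relaxes
    toward the volume-equivalent sphere.  Melt-pool parameters: substrate
    box below ``substrate_top``; ellipsoidal pool with semi-axes
    ``pool_axes`` translating from ``pool_start`` to ``pool_stop`` (x
    coordinate) at depth ``pool_z``; pool contrast =
    ``delta_value * pool_contrast_ratio``.
    """

    kind: str = "merging_droplets"
    grid_n: int = 32
    n_timepoints: int = 8
    delta_value: float = 1.0
    beta_value: float = 0.0
    seed: int = 0
    # static_ball
    ball_radius: float = 0.6
    # merging_droplets
    droplet_radii: tuple = (0.30, 0.26)
    droplet_separation: float = 1.0
    blend_k: float = 0.05
    relaxation_rate: float = 1.0
    # melt_pool
    substrate_top: float = -0.1
    substrate_half_width: float = 0.8
    pool_axes: tuple = (0.28, 0.18, 0.14)
    pool_start: float = -0.4
    pool_stop: float = 0.4
    pool_z: float = -0.12
    pool_contrast_ratio: float = 1.6

    def validate(self) -> None:
        if self.kind not in ("merging_droplets", "melt_pool", "static_ball"):
            raise PhantomSpecError(f"unknown phantom kind {self.kind!r}")
        if self.grid_n < 8:
            raise PhantomSpecError("grid_n must be >= 8")
        if self.n_timepoints < 1:
            raise PhantomSpecError("n_timepoints must be >= 1")
        if self.delta_value < 0 or self.beta_value < 0:
            raise PhantomSpecError("contrast levels must be >= 0")
        min_feature = 2.0 / self.grid_n * 2  # need >= 2 voxels across a radius
        if self.kind == "static_ball" and self.ball_radius < min_feature:
            raise PhantomSpecError("grid too small for the requested ball radius")
        if self.kind == "merging_droplets" and min(self.droplet_radii) < min_feature:
            raise PhantomSpecError("grid too small for the requested droplet radii")

    def to_dict(self) -> dict:
        return asdict(self)


def _grid(n: int):
    xs = voxel_centers(n)
    return np.meshgrid(xs, xs, xs, indexing="ij")


def _smin(a: np.ndarray, b: np.ndarray, k: float) -> np.ndarray:
    """Exponential smooth minimum; k -> 0 recovers min(a, b)."""
    return -k * np.logaddexp(-a / k, -b / k)


def make_phantom(spec: PhantomSpec) -> Volume4D:
    """Generate the deterministic ground-truth 4D volume for a spec."""
    spec.validate()
    n, tn = spec.grid_n, spec.n_timepoints
    gx, gy, gz = _grid(n)
    times = normalized_times(tn)
    frames = np.zeros((tn, n, n, n))

    if spec.kind == "static_ball":
        mask = gx**2 + gy**2 + gz**2 <= spec.ball_radius**2
        frames[:] = mask * spec.delta_value

    elif spec.kind == "merging_droplets":
        r1, r2 = spec.droplet_radii
        target_count = None
        for i in range(tn):
            s = i / (tn - 1) if tn > 1 else 0.0
            # approach then relax: the center distance shrinks linearly but
            # never reaches exact concentricity (relaxation asymptotes, and
            # an exactly concentric state would make whole lattice symmetry
            # classes degenerate in the iso-level solve)
            dist = spec.droplet_separation * max(
                0.02, 1.0 - s * spec.relaxation_rate
            )
            c1 = np.array([-dist / 2.0, 0.0, 0.0])
            c2 = np.array([+dist / 2.0, 0.0, 0.0])
            d1 = np.sqrt((gx - c1[0])**2 + (gy - c1[1])**2 + (gz - c1[2])**2) - r1
            d2 = np.sqrt((gx - c2[0])**2 + (gy - c2[1])**2 + (gz - c2[2])**2) - r2
            sdf = _smin(d1, d2, spec.blend_k)
            if target_count is None:
                target_count = int(np.count_nonzero(sdf < 0.0))
                tau = 0.0
            else:
                tau = _iso_level_for_count(sdf, target_count)
            frames[i] = (sdf < tau) * spec.delta_value

    else:  # melt_pool
        w = spec.substrate_half_width
        substrate = (
            (gz <= spec.substrate_top)
            & (np.abs(gx) <= w)
            & (np.abs(gy) <= w)
        )
        for i in range(tn):
            s = i / (tn - 1) if tn > 1 else 0.0
            cx = spec.pool_start + s * (spec.pool_stop - spec.pool_start)
            ax, ay, az = spec.pool_axes
            pool = (
                ((gx - cx) / ax) ** 2
                + (gy / ay) ** 2
                + ((gz - spec.pool_z) / az) ** 2
            ) <= 1.0
            fr = substrate * spec.delta_value
            fr = np.where(pool, spec.delta_value * spec.pool_contrast_ratio, fr)
            frames[i] = fr

    beta = None
    if spec.beta_value > 0:
        beta = frames / max(spec.delta_value, 1e-300) * spec.beta_value
    return Volume4D(
        delta=frames,
        beta=beta,
        times=times,
        voxel_size=2.0 / n,
        meta={"spec": spec.to_dict()},
    )


def _iso_level_for_count(sdf: np.ndarray, target: int, iters: int = 40) -> float:
    """Bisect the iso-level so that count(sdf < tau) matches target voxels.

    count is monotone non-decreasing in tau, so bisection conserves the
    phantom's occupied volume through shape changes to within one voxel
    shell; where the count jumps across a whole lattice symmetry class the
    closer side of the jump is taken.
    """
    lo, hi = -0.5, 0.5
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if np.count_nonzero(sdf < mid) < target:
            lo = mid
        else:
            hi = mid
    c_lo = np.count_nonzero(sdf < lo)
    c_hi = np.count_nonzero(sdf < hi)
    return lo if abs(c_lo - target) < abs(c_hi - target) else hi


def simulate_tomoscopy(
    phantom: Volume4D,
    frames_per_rotation: int,
    rotations: int = 1,
    noise: str = "none",
    noise_level: float = 0.0,
    seed: int | None = None,
    n_frames: int | None = None,
    geom: Geometry | None = None,
) -> ProjectionSet:
    """Virtual continuous-rotation acquisition of a 4D phantom.

    Frame j is acquired at cumulative angle j * 360 / frames_per_rotation;
    the phantom time axis is mapped onto the frame sequence by zero-order
    hold (each phantom state spans an equal run of frames, i.e. the sample
    is piecewise static).  Pixels come from the dense projection oracle,
    optionally corrupted by ``gaussian`` additive noise (sigma =
    ``noise_level`` in line-integral units) or a stylized ``poisson`` model
    (counts drawn at dose ``noise_level`` on exp(-value)).
    """
    if noise not in ("none", "gaussian", "poisson"):
        raise ValueError("noise must be 'none', 'gaussian', or 'poisson'")
    total = n_frames if n_frames is not None else rotations * frames_per_rotation
    if total < 1:
        raise ValueError("need at least one frame")
    tn = phantom.n_timepoints
    hold = max(total // tn, 1)
    n = phantom.grid_shape[0]
    if geom is None:
        geom = Geometry.for_cube(n)
    rng = np.random.default_rng(seed)
    frames = np.empty((total, geom.detector_rows, geom.detector_cols))
    theta = np.arange(total) * 360.0 / frames_per_rotation
    t_idx = np.minimum(np.arange(total) // hold, tn - 1)

    # identical (phantom state, angle mod 360) pairs render once
    cache: dict[tuple[int, float], np.ndarray] = {}
    for j in range(total):
        key = (int(t_idx[j]), round(theta[j] % 360.0, 9))
        if key not in cache:
            cache[key] = project_volume_oracle(
                phantom.delta[t_idx[j]], theta[j], geom
            )
        frames[j] = cache[key]

    if noise == "gaussian" and noise_level > 0:
        frames = frames + rng.normal(0.0, noise_level, size=frames.shape)
    elif noise == "poisson" and noise_level > 0:
        intensity = np.exp(-frames)
        counts = rng.poisson(noise_level * intensity)
        counts = np.maximum(counts, 1)
        frames = -np.log(counts / noise_level)

    return ProjectionSet(
        frames=frames,
        theta_deg=theta,
        time_index=t_idx,
        t_norm=phantom.times[t_idx],
        contrast_domain="delta_line_integral",
        pixel_size=geom.pixel_size,
        meta={
            "frames_per_rotation": frames_per_rotation,
            "noise": noise,
            "noise_level": noise_level,
        },
    )


def reference_descriptors(phantom: Volume4D, threshold: float | None = None) -> dict:
    """Deterministic per-time summaries used as test fixtures.

    Returns arrays of length T: connected-component count, occupied voxel
    volume (physical units), and centroid of the occupied region.
    """
    if threshold is None:
        threshold = 0.5 * phantom.delta.max()
    tn = phantom.n_timepoints
    counts = np.zeros(tn, dtype=int)
    volumes = np.zeros(tn)
    centroids = np.zeros((tn, 3))
    vox = phantom.voxel_size**3
    for i in range(tn):
        mask = phantom.delta[i] > threshold
        _, ncomp = ndimage.label(mask)
        counts[i] = ncomp
        volumes[i] = mask.sum() * vox
        if mask.any():
            centroids[i] = ndimage.center_of_mass(mask)
    return {"component_count": counts, "voxel_volume": volumes, "centroid": centroids}
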