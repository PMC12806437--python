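"""Parallel-beam X-ray forward model under the projection approximation.

A monochromatic plane wave traversing a weakly scattering object picks up,
per detector pixel, the line integrals of the refractive-index decrement
delta (phase) and of the attenuation index beta (absorption) along the ray:

    psi_exit = psi_0 * exp(-i k integral(delta - i beta) dz),  k = 2 pi / lambda

so the measurable intensity is exp(-2 k integral(beta) dz) and the phase shift
is -k integral(delta) dz.  Line integrals are the native contrast currency of
this package; conversions to intensity/phase are explicit operations.

Geometry convention: rotation axis is the volume z-axis, mapped to detector
rows.  At angle theta (degrees, counter-clockwise about +z) rays travel along
R_z(theta) @ (0, 1, 0); detector columns run along R_z(theta) @ (1, 0, 0).
The reconstruction volume is the normalized cube [-1, 1]^3; points outside
contribute zero (vacuum).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


from .scene import SceneModel, decode, query_features


@dataclass
class Geometry:
    """Parallel-beam detector geometry.

    ``pixel_size`` is the detector pitch in normalized volume units; a
    detector of N columns with pixel_size 2/N spans the full cube width.
    """

    detector_rows: int
    detector_cols: int
    pixel_size: float
    beam: str = "parallel"

    def __post_init__(self) -> None:
        if self.detector_rows < 1 or self.detector_cols < 1:
            raise ValueError("detector dims must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.beam != "parallel":
            raise ValueError("only parallel-beam geometry is supported")

    @property
    def n_pixels(self) -> int:
        return self.detector_rows * self.detector_cols

    @classmethod
    def for_cube(cls, n: int) -> "Geometry":
        """Square n x n detector exactly covering the [-1, 1] cube face."""
        return cls(detector_rows=n, detector_cols=n, pixel_size=2.0 / n)


@dataclass
class RayBundle:
    """One ray per detector pixel, flattened row-major.

    ``origin`` is the entry point into the normalized cube (or the central
    detector-plane point for rays that miss it), ``t_far`` the chord length;
    rays with ``t_far == 0`` miss the cube.
    """

    origin: np.ndarray      # (n, 3)
    direction: np.ndarray   # (n, 3), unit norm, identical for parallel beam
    t_far: np.ndarray       # (n,)

    @property
    def n_rays(self) -> int:
        return self.origin.shape[0]

    @property
    def chord(self) -> np.ndarray:
        return self.t_far


def generate_rays(geom: Geometry, theta_deg: float) -> RayBundle:
    """Rays for every detector pixel at rotation angle theta (degrees)."""
    th = np.deg2rad(theta_deg)
    d = np.array([-np.sin(th), np.cos(th), 0.0])
    u = np.array([np.cos(th), np.sin(th), 0.0])
    rows = np.arange(geom.detector_rows)
    cols = np.arange(geom.detector_cols)
    z = (rows - (geom.detector_rows - 1) / 2.0) * geom.pixel_size
    lat = (cols - (geom.detector_cols - 1) / 2.0) * geom.pixel_size
    zz, ll = np.meshgrid(z, lat, indexing="ij")
    p0 = ll.ravel()[:, None] * u + np.stack(
        [np.zeros(zz.size), np.zeros(zz.size), zz.ravel()], axis=1
    )
    t_near, t_far = _cube_intersect(p0, d)
    hit = np.isfinite(t_near) & (t_far > t_near)
    origin = p0.copy()
    origin[hit] += t_near[hit, None] * d
    chord = np.zeros(p0.shape[0])
    chord[hit] = t_far[hit] - t_near[hit]
    direction = np.broadcast_to(d, origin.shape).copy()
    return RayBundle(origin=origin, direction=direction, t_far=chord)


def _cube_intersect(p0: np.ndarray, d: np.ndarray):
    """Slab intersection of rays p0 + t*d with the cube [-1, 1]^3."""
    t_near = np.full(p0.shape[0], -np.inf)
    t_far = np.full(p0.shape[0], np.inf)
    for ax in range(3):
        if abs(d[ax]) < 1e-12:
            outside = (p0[:, ax] < -1.0) | (p0[:, ax] > 1.0)
            t_near = np.where(outside, np.inf, t_near)
        else:
            t0 = (-1.0 - p0[:, ax]) / d[ax]
            t1 = (1.0 - p0[:, ax]) / d[ax]
            lo, hi = np.minimum(t0, t1), np.maximum(t0, t1)
            t_near = np.maximum(t_near, lo)
            t_far = np.minimum(t_far, hi)
    t_far = np.maximum(t_far, t_near)  # misses collapse to zero-length chords
    return t_near, t_far


def sample_along_ray(
    rays: RayBundle,
    n_samples: int,
    mode: str = "uniform",
    seed: int | np.random.Generator | None = None,
):
    """Quadrature samples along each ray's chord through the cube.

    ``uniform`` places midpoints of equal sub-intervals (deterministic);
    ``stratified`` jitters one point per sub-interval.  Per-point weights
    are chord/n_samples, so weights along a ray sum to the chord length;
    rays that miss the cube get zero weights.

    Returns
    -------
    positions : ndarray (n_rays, n_samples, 3)
    weights : ndarray (n_rays, n_samples)
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if mode not in ("uniform", "stratified"):
        raise ValueError("mode must be 'uniform' or 'stratified'")
    n = rays.n_rays
    if mode == "stratified":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        offs = rng.uniform(0.0, 1.0, size=(n, n_samples))
    else:
        offs = np.full((n, n_samples), 0.5)
    frac = (np.arange(n_samples) + offs) / n_samples
    s = frac * rays.chord[:, None]
    positions = rays.origin[:, None, :] + s[..., None] * rays.direction[:, None, :]
    weights = np.broadcast_to(rays.chord[:, None] / n_samples, (n, n_samples)).copy()
    return positions, weights


@dataclass
class Radiograph:
    """A single projection image with acquisition metadata."""

    pixels: np.ndarray
    theta_deg: float
    t_norm: float = 0.0
    time_index: int = 0
    contrast_domain: str = "delta_line_integral"
    wavelength: float | None = None

    @property
    def wavenumber(self) -> float | None:
        return None if self.wavelength is None else 2.0 * np.pi / self.wavelength


def render_projection(
    scene: SceneModel,
    geom: Geometry,
    theta_deg: float,
    t: float,
    n_samples: int | None = None,
    seed: int | np.random.Generator | None = None,
    stratified: bool = False,
) -> list[Radiograph]:
    """Render radiograph(s) from the scene by line-integral quadrature.

    Returns one :class:`Radiograph` per output channel (delta line
    integrals first, beta second when the scene has two channels).  With
    ``stratified=False`` the midpoint rule makes rendering deterministic.
    """
    if n_samples is None:
        n_samples = max(scene.config.spatial_grid, scene.config.temporal_grid)
    rays = generate_rays(geom, theta_deg)
    pos, w = sample_along_ray(
        rays, n_samples, mode="stratified" if stratified else "uniform", seed=seed
    )
    pts = np.concatenate(
        [pos.reshape(-1, 3), np.full((pos.shape[0] * pos.shape[1], 1), float(t))],
        axis=1,
    )
    vals = decode(scene, query_features(scene, pts))
    c = scene.config.out_channels
    vals = vals.reshape(rays.n_rays, n_samples, c)
    imgs = (w[..., None] * vals).sum(axis=1)
    imgs = imgs.reshape(geom.detector_rows, geom.detector_cols, c)
    domains = ("delta_line_integral", "beta_line_integral")
    return [
        Radiograph(pixels=imgs[..., k], theta_deg=theta_deg, t_norm=float(t),
                   contrast_domain=domains[k])
        for k in range(c)
    ]


def intensity_from_line_integrals(beta_li: Radiograph, k: float) -> Radiograph:
    """Exit intensity exp(-2 k integral(beta) dz) for unit incident intensity."""
    if beta_li.contrast_domain != "beta_line_integral":
        raise ValueError("input must be in the beta_line_integral domain")
    return Radiograph(
        pixels=np.exp(-2.0 * k * beta_li.pixels),
        theta_deg=beta_li.theta_deg,
        t_norm=beta_li.t_norm,
        time_index=beta_li.time_index,
        contrast_domain="intensity",
        wavelength=2.0 * np.pi / k,
    )


def line_integrals_from_intensity(intensity: Radiograph, k: float) -> Radiograph:
    """Inverse of :func:`intensity_from_line_integrals`."""
    if intensity.contrast_domain != "intensity":
        raise ValueError("input must be in the intensity domain")
    if np.any(intensity.pixels <= 0):
        raise ValueError("intensity must be strictly positive")
    return Radiograph(
        pixels=-np.log(intensity.pixels) / (2.0 * k),
        theta_deg=intensity.theta_deg,
        t_norm=intensity.t_norm,
        time_index=intensity.time_index,
        contrast_domain="beta_line_integral",
        wavelength=2.0 * np.pi / k,
    )


def phase_from_line_integrals(delta_li: Radiograph, k: float) -> Radiograph:
    """Phase shift phi = -k integral(delta) dz."""
    if delta_li.contrast_domain != "delta_line_integral":
        raise ValueError("input must be in the delta_line_integral domain")
    return Radiograph(
        pixels=-k * delta_li.pixels,
        theta_deg=delta_li.theta_deg,
        t_norm=delta_li.t_norm,
        time_index=delta_li.time_index,
        contrast_domain="phase",
        wavelength=2.0 * np.pi / k,
    )


def project_volume_oracle(
    volume: np.ndarray,
    theta_deg: float,
    geom: Geometry,
    n_samples: int | None = None,
) -> np.ndarray:
    """Brute-force discrete Radon transform of a dense volume.

    Dense deterministic midpoint quadrature with trilinear interpolation of
    the (nx, ny, nz) voxel grid (cell-centered on [-1, 1]^3).  Each voxel
    covers its full cell, so interpolation clamps to the edge cell within
    the cube; everything outside the cube contributes zero because rays
    integrate only over their cube chord.  Serves both as the phantom
    projection simulator and as the reference the stochastic renderer is
    tested against.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError("volume must be 3D")
    if n_samples is None:
        n_samples = 2 * max(volume.shape)
    rays = generate_rays(geom, theta_deg)
    pos, w = sample_along_ray(rays, n_samples, mode="uniform")
    shape = np.array(volume.shape, dtype=float)
    # cell-centered index: coord -1 + (2i+1)/n  ->  i = (coord+1)*n/2 - 1/2
    idx = (pos + 1.0) * (shape / 2.0) - 0.5
    vals = ndimage.map_coordinates(
        volume, idx.reshape(-1, 3).T, order=1, mode="nearest"
    ).reshape(pos.shape[:2])
    img = (w * vals).sum(axis=1)
    return img.reshape(geom.detector_rows, geom.detector_cols)
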