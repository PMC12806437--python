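"""Radiograph conditioning before reconstruction.

The chain mirrors standard synchrotron practice: flat-field correction of
raw frames to transmission, single-distance phase retrieval for homogeneous
objects (transport-of-intensity, Paganin-style low-pass filter in Fourier
space), multiplicative normalization enforcing the parallel-beam Radon mass
property within each time point, and rebinning of repeated 0-180 degree
blocks into 0-360 degree blocks (half the time points, twice the
projections per point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

from .data import ProjectionSet


class PreprocessError(ValueError):
    pass


def flat_field_correct(
    raw: np.ndarray,
    flat: np.ndarray,
    dark: np.ndarray | None = None,
    floor: float = 1e-9,
) -> np.ndarray:
    """Transmission (raw - dark) / (flat - dark), clipped below at ``floor``.

    ``dark`` defaults to zero.  Raises if any denominator pixel is
    non-positive (dead detector region), reporting the offending count.
    """
    raw = np.asarray(raw, dtype=np.float64)
    flat = np.asarray(flat, dtype=np.float64)
    if raw.shape != flat.shape:
        raise PreprocessError("raw and flat shapes differ")
    if dark is None:
        dark = np.zeros_like(flat)
    else:
        dark = np.asarray(dark, dtype=np.float64)
        if dark.shape != flat.shape:
            raise PreprocessError("dark and flat shapes differ")
    denom = flat - dark
    bad = int(np.count_nonzero(denom <= 0))
    if bad:
        raise PreprocessError(f"{bad} non-positive (flat - dark) pixels")
    return np.maximum((raw - dark) / denom, floor)


@dataclass
class PhaseRetrievalParams:
    """Single-material transport-of-intensity retrieval parameters.

    All lengths share one unit (e.g. meters).  ``mu`` is the linear
    attenuation coefficient of the material, mu = 4 pi beta / lambda, used
    only as the output prefactor -(1/mu) ln(.); the Fourier filter itself
    depends on the delta/beta ratio, the propagation distance and the
    wavelength.
    """

    delta_over_beta: float
    distance: float
    wavelength: float
    pixel_size: float
    mu: float = 1.0

    def __post_init__(self) -> None:
        for name in ("delta_over_beta", "wavelength", "pixel_size", "mu"):
            if getattr(self, name) <= 0:
                raise PreprocessError(f"{name} must be positive")
        if self.distance < 0:
            raise PreprocessError("distance must be >= 0")


def paganin_filter(shape: tuple[int, int], params: PhaseRetrievalParams) -> np.ndarray:
    """Fourier-domain denominator 1 + (R * delta/beta * lambda / (4 pi)) |2 pi f|^2.

    Frequencies f are in cycles per physical length, derived from the pixel
    size; at zero distance the filter is identically 1.
    """
    fy = sp_fft.fftfreq(shape[0], d=params.pixel_size)
    fx = sp_fft.fftfreq(shape[1], d=params.pixel_size)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    coef = params.distance * params.delta_over_beta * params.wavelength / (4.0 * np.pi)
    return 1.0 + coef * (2.0 * np.pi) ** 2 * f2


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def paganin_retrieve(
    transmission: np.ndarray,
    params: PhaseRetrievalParams,
    pad: bool = True,
    floor: float = 1e-9,
) -> np.ndarray:
    """Thickness-proportional projection from one defocused transmission image.

    Output is -(1/mu) ln( IFFT2[ FFT2[I] / D ] ) with the single-material
    filter D of :func:`paganin_filter`.  With ``pad`` (default) the image is
    symmetrically padded to the next power of two to suppress FFT
    wrap-around.  At distance 0 the filter collapses to 1 and the result is
    the pure absorption projection -ln(I)/mu.  Non-positive filtered
    intensities are clipped to ``floor`` with a warning reporting the count.
    """
    img = np.asarray(transmission, dtype=np.float64)
    if img.ndim != 2:
        raise PreprocessError("transmission must be a 2D image")
    if np.any(img <= 0):
        raise PreprocessError("transmission must be strictly positive")
    h, w = img.shape
    if pad:
        ph, pw = _next_pow2(h), _next_pow2(w)
        py, px = ph - h, pw - w
        work = np.pad(img, ((0, py), (0, px)), mode="symmetric")
    else:
        work = img
    filt = paganin_filter(work.shape, params)
    filtered = sp_fft.ifft2(sp_fft.fft2(work) / filt).real[:h, :w]
    n_bad = int(np.count_nonzero(filtered <= 0))
    if n_bad:
        warnings.warn(f"clipped {n_bad} non-positive filtered pixels")
        filtered = np.maximum(filtered, floor)
    return -np.log(filtered) / params.mu


def radon_sum_normalize(projections: ProjectionSet):
    """Scale frames so each one's pixel sum equals its time group's mean sum.

    For parallel-beam projections of a fully contained object, the total
    integral of every projection at one time point is the same (Radon mass
    property); residual per-frame deviations come from flux drift or noise
    and are removed multiplicatively.  Returns the normalized set and the
    per-frame scale factors for audit.  Idempotent.
    """
    sums = projections.frames.sum(axis=(1, 2))
    zero = np.nonzero(sums == 0)[0]
    if zero.size:
        raise PreprocessError(f"frame {zero[0]} has zero pixel sum")
    factors = np.empty_like(sums)
    for ti in np.unique(projections.time_index):
        grp = projections.time_index == ti
        factors[grp] = sums[grp].mean() / sums[grp]
    out = projections.select(slice(None))
    out.frames = projections.frames * factors[:, None, None]
    return out, factors


def rebin_half_to_full_rotation(
    stack: np.ndarray, angles_deg: np.ndarray | None = None
):
    """Merge consecutive 0-180 degree time blocks into 0-360 degree blocks.

    A (2T, P, H, W) stack of 180-degree blocks becomes (T, 2P, H, W): block
    pairs are concatenated along the projection axis and the per-block angle
    table (P,) is extended to (2P,) over 0-360.  Total frame count is
    preserved.  Raises on an odd number of time blocks.
    """
    stack = np.asarray(stack)
    if stack.ndim != 4:
        raise PreprocessError("stack must have shape (2T, P, H, W)")
    two_t, p, h, w = stack.shape
    if two_t % 2 != 0:
        raise PreprocessError("number of 180-degree time blocks must be even")
    out = stack.reshape(two_t // 2, 2 * p, h, w)
    if angles_deg is None:
        return out
    angles_deg = np.asarray(angles_deg, dtype=np.float64)
    if angles_deg.shape != (p,):
        raise PreprocessError("angles_deg must have one entry per in-block frame")
    new_angles = np.concatenate([angles_deg, angles_deg + 180.0])
    return out, new_angles
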