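"""In-memory containers for projection stacks and 4D volumes, with HDF5/TIFF I/O.

The canonical on-disk layout for a projection stack is a single HDF5 file with
datasets ``/projections`` (n_frames, rows, cols), ``/theta_deg`` (unwrapped,
cumulative rotation angle per frame), ``/time_index`` and ``/t_norm``, plus
scalar attributes for the contrast domain and detector pixel size.  Multi-page
TIFF with a CSV sidecar table is offered for interchange with imaging tools.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile

CONTRAST_DOMAINS = (
    "delta_line_integral",
    "beta_line_integral",
    "intensity",
    "phase",
)


@dataclass
class ProjectionSet:
    """Angle- and time-stamped radiograph stack.

    Parameters
    ----------
    frames : ndarray, shape (n, rows, cols)
        Pixel data, one radiograph per frame, in the units implied by
        ``contrast_domain`` (line integrals of the refractive index
        decrement by default).
    theta_deg : ndarray, shape (n,)
        Unwrapped rotation angle of each frame in degrees.  Under continuous
        rotation this grows without bound; use :meth:`theta_mod` for the
        angle folded into [0, 360).
    time_index : ndarray, shape (n,)
        Integer time-point label of each frame.
    t_norm : ndarray, shape (n,)
        Normalized time stamp in [-1, 1] used by the scene model.
    contrast_domain : str
        One of ``delta_line_integral``, ``beta_line_integral``,
        ``intensity``, ``phase``.
    pixel_size : float
        Detector pixel pitch in normalized volume units (the reconstruction
        cube spans [-1, 1]).
    """

    frames: np.ndarray
    theta_deg: np.ndarray
    time_index: np.ndarray
    t_norm: np.ndarray
    contrast_domain: str = "delta_line_integral"
    pixel_size: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.theta_deg = np.asarray(self.theta_deg, dtype=np.float64)
        self.time_index = np.asarray(self.time_index, dtype=np.int64)
        self.t_norm = np.asarray(self.t_norm, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (n, rows, cols)")
        n = self.frames.shape[0]
        for name in ("theta_deg", "time_index", "t_norm"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
        if self.contrast_domain not in CONTRAST_DOMAINS:
            raise ValueError(f"unknown contrast_domain {self.contrast_domain!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def detector_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def theta_mod(self) -> np.ndarray:
        """Per-frame angle folded into [0, 360) degrees."""
        return np.mod(self.theta_deg, 360.0)

    def select(self, idx) -> "ProjectionSet":
        """Pure frame selection; pixels and angles are untouched."""
        return ProjectionSet(
            frames=self.frames[idx],
            theta_deg=self.theta_deg[idx],
            time_index=self.time_index[idx],
            t_norm=self.t_norm[idx],
            contrast_domain=self.contrast_domain,
            pixel_size=self.pixel_size,
            meta=dict(self.meta),
        )

    # ------------------------------------------------------------------ I/O
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("projections", data=self.frames, track_times=False)
            f.create_dataset("theta_deg", data=self.theta_deg, track_times=False)
            f.create_dataset("time_index", data=self.time_index, track_times=False)
            f.create_dataset("t_norm", data=self.t_norm, track_times=False)
            f.attrs["contrast_domain"] = self.contrast_domain
            f.attrs["pixel_size"] = self.pixel_size
            f.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def from_hdf5(cls, path) -> "ProjectionSet":
        with h5py.File(path, "r") as f:
            return cls(
                frames=f["projections"][()],
                theta_deg=f["theta_deg"][()],
                time_index=f["time_index"][()],
                t_norm=f["t_norm"][()],
                contrast_domain=str(f.attrs["contrast_domain"]),
                pixel_size=float(f.attrs["pixel_size"]),
                meta=json.loads(f.attrs.get("meta", "{}")),
            )

    def to_tiff(self, tiff_path, table_path) -> None:
        """Multi-page TIFF of the pixel data plus a CSV sidecar table."""
        tifffile.imwrite(tiff_path, self.frames.astype(np.float32))
        with open(table_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["frame", "theta_deg", "time_index", "t_norm"])
            for j in range(self.n_frames):
                w.writerow([j, self.theta_deg[j], self.time_index[j], self.t_norm[j]])

    @classmethod
    def from_tiff(cls, tiff_path, table_path, contrast_domain="delta_line_integral",
                  pixel_size=1.0) -> "ProjectionSet":
        frames = tifffile.imread(tiff_path).astype(np.float64)
        if frames.ndim == 2:
            frames = frames[None]
        rows = np.genfromtxt(table_path, delimiter=",", names=True)
        rows = np.atleast_1d(rows)
        return cls(
            frames=frames,
            theta_deg=np.asarray(rows["theta_deg"], dtype=float),
            time_index=np.asarray(rows["time_index"], dtype=int),
            t_norm=np.asarray(rows["t_norm"], dtype=float),
            contrast_domain=contrast_domain,
            pixel_size=pixel_size,
        )


@dataclass
class Volume4D:
    """Dense time series of refractive-index volumes.

    ``delta`` holds the refractive-index decrement on a (T, nx, ny, nz) grid
    of voxel centers spanning the normalized cube [-1, 1]^3; ``beta`` (same
    shape) is the attenuation index and may be absent.
    """

    delta: np.ndarray
    times: np.ndarray
    voxel_size: float
    beta: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.delta.ndim != 4:
            raise ValueError("delta must have shape (T, nx, ny, nz)")
        if self.times.shape != (self.delta.shape[0],):
            raise ValueError("times must have one entry per time point")
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=np.float64)
            if self.beta.shape != self.delta.shape:
                raise ValueError("beta must match delta's shape")

    @property
    def n_timepoints(self) -> int:
        return self.delta.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.delta.shape[1:]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("delta", data=self.delta, track_times=False)
            if self.beta is not None:
                f.create_dataset("beta", data=self.beta, track_times=False)
            f.create_dataset("times", data=self.times, track_times=False)
            f.attrs["voxel_size"] = self.voxel_size
            f.attrs["meta"] = json.dumps(self.meta)

    @classmethod
    def from_hdf5(cls, path) -> "Volume4D":
        with h5py.File(path, "r") as f:
            return cls(
                delta=f["delta"][()],
                beta=f["beta"][()] if "beta" in f else None,
                times=f["times"][()],
                voxel_size=float(f.attrs["voxel_size"]),
                meta=json.loads(f.attrs.get("meta", "{}")),
            )


def voxel_centers(n: int) -> np.ndarray:
    """Cell-centered voxel coordinates on [-1, 1] for an n-point axis."""
    return -1.0 + (2.0 * np.arange(n) + 1.0) / n


def normalized_times(n_timepoints: int) -> np.ndarray:
    """Cell-centered normalized time stamps in [-1, 1] for T time points."""
    return -1.0 + (2.0 * np.arange(n_timepoints) + 1.0) / n_timepoints
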