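"""Time-resolved 3-D, 3-component velocity fields on a regular voxel grid.

The central in-memory object of the package is :class:`VelocityField4D`:
one cardiac cycle of phase-contrast velocity data, stored as a
``(frames, nx, ny, nz, 3)`` array in cm/s together with the physical
metadata (voxel spacing, frame duration, velocity-encoding limit) that
every downstream stage needs.

Conventions
-----------
* World coordinates are RAS millimetres; the voxel with index ``(i, j, k)``
  has its centre at ``((i, j, k) + 0.5) * spacing_mm``.
* Frames are 0-based and, for ``cyclic=True`` fields, cover exactly one
  R-R interval: frame ``n_frames`` wraps back to frame 0.
* Velocities are stored in cm/s; conversions to mm per frame (the natural
  unit of the pathline integrator) go through :meth:`VelocityField4D.mm_per_frame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["VelocityField4D"]


@dataclass
class VelocityField4D:
    """One cardiac cycle of 3-D, 3-component velocity data.

    Parameters
    ----------
    values : ndarray, shape (n_frames, nx, ny, nz, 3)
        Velocities in cm/s.
    spacing_mm : array-like of 3 floats
        Voxel edge lengths in mm.
    frame_ms : float
        Temporal resolution (duration of one frame) in ms.
    venc_cm_s : float
        Velocity-encoding limit; acquisition-faithful data satisfy
        ``|v| <= venc`` and may exceed it only after anti-aliasing.
    cyclic : bool
        Whether the frames tile the cardiac cycle periodically.
    """

    values: np.ndarray
    spacing_mm: np.ndarray
    frame_ms: float
    venc_cm_s: float
    cyclic: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=np.float64).reshape(3)
        if self.values.ndim != 5 or self.values.shape[-1] != 3:
            raise ValueError(
                f"values must have shape (frames, nx, ny, nz, 3), got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("velocity values must be finite")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing_mm must be strictly positive")
        if self.frame_ms <= 0:
            raise ValueError("frame_ms must be strictly positive")
        if self.venc_cm_s <= 0:
            raise ValueError("venc_cm_s must be strictly positive")

    # -- basic geometry -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape[1:4]

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size of the grid hull ``[0, n*spacing]`` along each axis."""
        return np.asarray(self.grid_shape) * self.spacing_mm

    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-D arrays of voxel-centre coordinates along each axis (mm)."""
        return tuple(
            (np.arange(n) + 0.5) * s for n, s in zip(self.grid_shape, self.spacing_mm)
        )

    # -- unit helpers ---------------------------------------------------
    def mm_per_frame(self, v_cm_s: np.ndarray) -> np.ndarray:
        """Convert velocities in cm/s to displacement per frame in mm."""
        return np.asarray(v_cm_s) * (self.frame_ms / 100.0)

    def cm_s_from_mm_per_frame(self, v_mm_frame: np.ndarray) -> np.ndarray:
        return np.asarray(v_mm_frame) * (100.0 / self.frame_ms)

    def with_values(self, values: np.ndarray) -> "VelocityField4D":
        """Copy of this field with replaced velocity data (same metadata)."""
        return replace(self, values=np.asarray(values, dtype=np.float64))

    def copy(self) -> "VelocityField4D":
        return replace(self, values=self.values.copy())
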