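"""Velocity sampling at arbitrary positions and times.

Trilinear interpolation in space (voxel centres at ``(index + 0.5) *
spacing``), linear interpolation in time with cyclic wrap between the last
and first frame. This is the single interpolation contract shared by the
pathline integrator, the dense advection oracle of the phantom module, and
valve-plane flux integration, so that all of them see the same continuous
field.
"""

from __future__ import annotations

import numpy as np

from .field import VelocityField4D

__all__ = ["sample_velocity"]


def _blend_frames(field: VelocityField4D, time_frames: float) -> np.ndarray:
    """Linearly time-interpolated (nx, ny, nz, 3) velocity volume."""
    T = field.n_frames
    t = float(time_frames)
    if field.cyclic:
        t = t % T
        f0 = int(np.floor(t)) % T
        w = t - np.floor(t)
        f1 = (f0 + 1) % T
    else:
        t = min(max(t, 0.0), T - 1.0)
        f0 = int(np.floor(t))
        w = t - f0
        f1 = min(f0 + 1, T - 1)
    if w == 0.0:
        return field.values[f0]
    return (1.0 - w) * field.values[f0] + w * field.values[f1]


def _trilinear(
    volume: np.ndarray,
    pos_mm: np.ndarray,
    spacing_mm: np.ndarray,
    mode: str,
) -> np.ndarray:
    dims = np.asarray(volume.shape[:3])
    u = pos_mm / spacing_mm - 0.5  # continuous voxel index
    i0 = np.floor(u).astype(np.int64)
    frac = u - i0

    out = np.zeros((pos_mm.shape[0], 3), dtype=np.float64)
    for corner in range(8):
        offs = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        idx = i0 + offs
        w = np.prod(np.where(offs == 1, frac, 1.0 - frac), axis=1)
        if mode == "hold":
            idxc = np.clip(idx, 0, dims - 1)
            out += w[:, None] * volume[idxc[:, 0], idxc[:, 1], idxc[:, 2]]
        else:  # zero padding outside the grid
            valid = np.all((idx >= 0) & (idx < dims), axis=1)
            if np.any(valid):
                iv = idx[valid]
                out[valid] += w[valid, None] * volume[iv[:, 0], iv[:, 1], iv[:, 2]]
    return out


def sample_velocity(
    field: VelocityField4D,
    position_mm: np.ndarray,
    time_frames: float,
    mode: str = "zero",
) -> np.ndarray:
    """Sample the velocity field (cm/s) at world positions and a real time.

    Parameters
    ----------
    field : VelocityField4D
    position_mm : ndarray, shape (N, 3) or (3,)
        World coordinates in mm. Positions outside the grid hull are handled
        according to ``mode``.
    time_frames : float
        Time in frame units; cyclic fields wrap modulo ``n_frames``.
    mode : {"zero", "hold"}
        Out-of-hull behaviour: blend with zeros beyond the outermost voxel
        centres ("zero", default) or clamp to the nearest edge value ("hold").

    Returns
    -------
    ndarray of the same leading shape as ``position_mm`` with 3 components.
    """
    if mode not in ("zero", "hold"):
        raise ValueError(f"unknown out-of-domain mode {mode!r}")
    pos = np.asarray(position_mm, dtype=np.float64)
    single = pos.ndim == 1
    pos = np.atleast_2d(pos)
    volume = _blend_frames(field, time_frames)
    out = _trilinear(volume, pos, field.spacing_mm, mode)
    return out[0] if single else out
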