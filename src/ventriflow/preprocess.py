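"""Background phase-offset correction and velocity anti-aliasing.

Phase-contrast velocity data carry a slowly varying background offset from
eddy currents and uncompensated concomitant (Maxwell) gradient fields. The
standard remedy, implemented here, fits a low-order spatial polynomial to
the time-averaged velocity of static tissue and subtracts it everywhere.
Without access to the sequence's gradient waveforms the Maxwell contribution
cannot be isolated, so it is folded into the same polynomial model.

Velocities beyond the encoding limit VENC wrap by multiples of 2*VENC.
:func:`unalias` applies a single-wrap correction by neighbourhood-median
voting: a voxel is shifted by +-2*VENC when that brings it closer to the
median of its 6-neighbourhood, iterated over the volume for a bounded
number of sweeps. The method needs an unwrapped anchor next to every
aliased region; a region that wraps uniformly together with all of its
neighbours is unrecoverable by any local criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .field import VelocityField4D

__all__ = [
    "OffsetModel",
    "OffsetFitError",
    "monomial_exponents",
    "fit_phase_offset",
    "evaluate_offset",
    "correct_phase_offset",
    "UnaliasResult",
    "unalias",
]


class OffsetFitError(RuntimeError):
    """Degenerate static-mask geometry: the polynomial fit is rank deficient."""


def monomial_exponents(order: int) -> list[tuple[int, int, int]]:
    """Monomial exponent triples up to total degree ``order``.

    Ordered by total degree, then lexicographically in (x, y, z), so degree
    one reads (1, x, y, z) and a coefficient vector ``(a, b, c, d)`` means
    ``a + b*x + c*y + d*z``.
    """
    if not 0 <= order <= 3:
        raise ValueError("polynomial order must be in 0..3")
    out = []
    for total in range(order + 1):
        for i in range(total, -1, -1):
            for j in range(total - i, -1, -1):
                out.append((i, j, total - i - j))
    return out


def _design_matrix(coords_mm: np.ndarray, order: int) -> np.ndarray:
    exps = monomial_exponents(order)
    cols = [
        coords_mm[:, 0] ** i * coords_mm[:, 1] ** j * coords_mm[:, 2] ** k
        for (i, j, k) in exps
    ]
    return np.stack(cols, axis=1)


@dataclass
class OffsetModel:
    """Per-component spatial polynomial offset, in cm/s per mm^k.

    ``coeffs`` has shape (3, n_monomials) with monomials ordered as in
    :func:`monomial_exponents`; ``fit_rms`` is the per-component residual
    RMS of the fit on static voxels.
    """

    order: int
    coeffs: np.ndarray
    fit_rms: np.ndarray
    grid_shape: tuple[int, int, int]
    spacing_mm: np.ndarray

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64)
        k = len(monomial_exponents(self.order))
        if self.coeffs.shape != (3, k):
            raise ValueError(
                f"coefficient count {self.coeffs.shape} does not match degree-"
                f"{self.order} monomial count (3, {k})"
            )


def fit_phase_offset(
    field: VelocityField4D, static_mask: np.ndarray, order: int = 1
) -> OffsetModel:
    """Least-squares polynomial fit to time-averaged static-tissue velocity.

    The offset is assumed stationary over the cycle (standard practice for
    eddy-current offsets), so velocities are averaged over frames before the
    per-component fit. Requires at least 10 static voxels per fitted
    coefficient.
    """
    mask = np.asarray(static_mask).astype(bool)
    if mask.shape != field.grid_shape:
        raise ValueError("static_mask shape does not match the field grid")
    n_coef = len(monomial_exponents(order))
    n_static = int(mask.sum())
    if n_static < 10 * n_coef:
        raise ValueError(
            f"static mask has {n_static} voxels; need >= {10 * n_coef} "
            f"for a degree-{order} fit"
        )
    cx, cy, cz = field.voxel_centers_mm()
    ii, jj, kk = np.nonzero(mask)
    coords = np.stack([cx[ii], cy[jj], cz[kk]], axis=1)
    X = _design_matrix(coords, order)
    vmean = field.values.mean(axis=0)[mask]  # (M, 3)
    coeffs, _, rank, _ = np.linalg.lstsq(X, vmean, rcond=None)
    if rank < n_coef:
        raise OffsetFitError(
            f"design matrix rank {rank} < {n_coef}: static-mask geometry is degenerate"
        )
    resid = vmean - X @ coeffs
    rms = np.sqrt(np.mean(resid**2, axis=0))
    return OffsetModel(
        order=order,
        coeffs=coeffs.T,
        fit_rms=rms,
        grid_shape=field.grid_shape,
        spacing_mm=field.spacing_mm.copy(),
    )


def evaluate_offset(model: OffsetModel, field: VelocityField4D) -> np.ndarray:
    """Modeled offset volume, shape (nx, ny, nz, 3), in cm/s."""
    cx, cy, cz = field.voxel_centers_mm()
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
    out = np.zeros(field.grid_shape + (3,))
    for m, (i, j, k) in enumerate(monomial_exponents(model.order)):
        mono = X**i * Y**j * Z**k
        out += mono[..., None] * model.coeffs[:, m]
    return out


def correct_phase_offset(field: VelocityField4D, model: OffsetModel) -> VelocityField4D:
    """Subtract the modeled offset at every voxel and frame.

    Not idempotent: applying a non-zero model twice subtracts it twice.
    """
    if model.grid_shape != field.grid_shape or not np.allclose(
        model.spacing_mm, field.spacing_mm
    ):
        raise ValueError("offset model was fitted on an incompatible grid")
    offset = evaluate_offset(model, field)
    return field.with_values(field.values - offset[None])


_FOOTPRINT = np.zeros((3, 3, 3), dtype=bool)
_FOOTPRINT[0, 1, 1] = _FOOTPRINT[2, 1, 1] = True
_FOOTPRINT[1, 0, 1] = _FOOTPRINT[1, 2, 1] = True
_FOOTPRINT[1, 1, 0] = _FOOTPRINT[1, 1, 2] = True


@dataclass
class UnaliasResult:
    field: VelocityField4D
    n_changed: int
    sweeps: int
    converged: bool


def unalias(field: VelocityField4D, max_sweeps: int = 5) -> UnaliasResult:
    """Single-wrap anti-aliasing by 6-neighbourhood median voting.

    Every voxel value may be shifted by exactly one multiple of +-2*VENC
    when the shift reduces its deviation from the median of its six face
    neighbours (computed per frame and per velocity component); sweeps
    repeat until no voxel changes or ``max_sweeps`` is reached. Fields with
    no wrap-scale neighbour jumps are returned unchanged.
    """
    two_venc = 2.0 * field.venc_cm_s
    vals = field.values.copy()
    total_changed = 0
    sweeps = 0
    converged = False
    for sweep in range(max_sweeps):
        sweeps = sweep + 1
        changed = 0
        for t in range(field.n_frames):
            for c in range(3):
                v = vals[t, ..., c]
                med = ndimage.median_filter(v, footprint=_FOOTPRINT, mode="nearest")
                dev0 = np.abs(v - med)
                dev_up = np.abs(v + two_venc - med)
                dev_dn = np.abs(v - two_venc - med)
                up = (dev_up < dev0) & (dev_up <= dev_dn)
                dn = (dev_dn < dev0) & (dev_dn < dev_up)
                n = int(up.sum() + dn.sum())
                if n:
                    v[up] += two_venc
                    v[dn] -= two_venc
                    changed += n
        total_changed += changed
        if changed == 0:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"unalias did not converge within {max_sweeps} sweeps "
            f"({total_changed} voxels changed in total)",
            RuntimeWarning,
            stacklevel=2,
        )
    return UnaliasResult(
        field=field.with_values(vals),
        n_changed=total_changed,
        sweeps=sweeps,
        converged=converged,
    )
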