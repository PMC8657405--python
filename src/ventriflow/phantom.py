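"""Synthetic 4-D flow phantoms with known flow-component ground truth.

Three phantom families stand in for acquired patient data:

* a straight **tube** with uniform axial flow, whose direct-flow /
  retained-inflow / delayed-ejection / residual-volume split is known in
  closed form from seed depth versus per-phase displacement;
* a **solid-body rotation** chamber whose closed streamlines never cross a
  valve (all residual volume; analytic circular orbits for integrator
  checks);
* a half-ellipsoid **LV** whose wall follows a smooth diastolic-filling /
  systolic-ejection volume curve, with interior velocity obtained from a
  discrete potential-flow solve of the continuity constraint, inflow
  confined to a mitral orifice during diastole and outflow to an aortic
  orifice during systole. Its ground truth is computed by an independent
  dense Euler advection (default 100 substeps per frame) at build time.

A corruption operator adds a polynomial eddy-current-like phase offset,
Gaussian velocity noise and single-wrap VENC aliasing, and a cohort
generator draws per-subject component-fraction tables with a two-group
(healthy control vs. paroxysmal atrial fibrillation) structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.linalg import cg

from .anatomy import PhaseMap, ValvePlane
from .field import VelocityField4D
from .interpolate import sample_velocity
from .preprocess import monomial_exponents

__all__ = [
    "GroundTruth",
    "PhantomBundle",
    "CorruptionSpec",
    "make_tube_phantom",
    "make_rotation_phantom",
    "make_lv_phantom",
    "corrupt_field",
    "make_synthetic_cohort",
    "make_two_group_cohort",
]

COMPONENTS = ("df", "ri", "de", "rv")


@dataclass
class GroundTruth:
    """Known four-component decomposition of the seeded end-diastolic volume."""

    df_pct: float
    ri_pct: float
    de_pct: float
    rv_pct: float
    df_ml: float
    ri_ml: float
    de_ml: float
    rv_ml: float
    seeded_volume_ml: float
    provenance: str  # "analytic" | "dense-oracle"

    def __post_init__(self) -> None:
        pct = self.df_pct + self.ri_pct + self.de_pct + self.rv_pct
        vol = self.df_ml + self.ri_ml + self.de_ml + self.rv_ml
        if abs(pct - 100.0) > 1e-9:
            raise ValueError(f"component percents sum to {pct}, not 100")
        if abs(vol - self.seeded_volume_ml) > 1e-9:
            raise ValueError("component volumes do not sum to the seeded volume")

    def pct_vector(self) -> np.ndarray:
        return np.array([self.df_pct, self.ri_pct, self.de_pct, self.rv_pct])

    @classmethod
    def from_counts(
        cls, n_df: int, n_ri: int, n_de: int, n_rv: int, voxel_volume_ml: float, provenance: str
    ) -> "GroundTruth":
        total = n_df + n_ri + n_de + n_rv
        if total == 0:
            raise ValueError("no seeds")
        pct = [100.0 * n / total for n in (n_df, n_ri, n_de, n_rv)]
        # close the rounding gap exactly on the largest component
        gap = 100.0 - sum(pct)
        pct[int(np.argmax(pct))] += gap
        ml = [n * voxel_volume_ml for n in (n_df, n_ri, n_de, n_rv)]
        seeded = total * voxel_volume_ml
        ml[int(np.argmax(ml))] += seeded - sum(ml)
        return cls(*pct, *ml, seeded_volume_ml=seeded, provenance=provenance)


@dataclass
class PhantomBundle:
    """A complete synthetic study: field, masks, valve planes, phases, truth."""

    field: VelocityField4D
    lv_mask: np.ndarray  # (frames, nx, ny, nz) bool
    static_mask: np.ndarray  # (nx, ny, nz) bool
    mitral: ValvePlane
    aortic: ValvePlane
    truth: GroundTruth
    phases: PhaseMap
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lv_mask = np.asarray(self.lv_mask).astype(bool)
        self.static_mask = np.asarray(self.static_mask).astype(bool)
        if self.lv_mask.shape != (self.field.n_frames,) + self.field.grid_shape:
            raise ValueError("lv_mask must be (frames,) + grid shape")
        if self.static_mask.shape != self.field.grid_shape:
            raise ValueError("static_mask must match the grid shape")
        if np.any(self.lv_mask & self.static_mask[None]):
            raise ValueError("lv_mask and static_mask overlap")
        if np.any(self.field.values[:, self.static_mask, :] != 0.0):
            raise ValueError("static-mask voxels must carry zero velocity")


def _cross_section_center_mm(n: int, spacing: float) -> float:
    return n * spacing / 2.0


# ---------------------------------------------------------------------------
# tube phantom
# ---------------------------------------------------------------------------


def _tube_speed_profile(n_diastole: int, n_systole: int, modulated: bool) -> np.ndarray:
    """Per-frame speed multipliers w with exact per-phase trapezoid integrals.

    With temporal modulation the profile vanishes at the phase boundaries
    (giving detectable IVR/end-diastole dips in the flux curves) while the
    piecewise-linear time interpolation keeps each phase's displacement
    integral exactly ``n_phase`` frames' worth, so the closed-form component
    split is unchanged. RK4 integrates piecewise-linear-in-time uniform
    fields exactly when steps align with frame boundaries.
    """
    T = n_diastole + n_systole
    if not modulated:
        return np.ones(T)
    w = np.zeros(T + 1)  # index T is the cyclic image of index 0
    i = np.arange(n_diastole + 1)
    w[: n_diastole + 1] = np.sin(np.pi * i / n_diastole)
    j = np.arange(n_systole + 1)
    w[n_diastole:] = np.sin(np.pi * j / n_systole)
    # rescale each phase so the trapezoid integral equals the frame count
    s_d = np.trapezoid(w[: n_diastole + 1])
    s_s = np.trapezoid(w[n_diastole:])
    w[: n_diastole + 1] *= n_diastole / s_d
    w[n_diastole:] *= n_systole / s_s
    w[n_diastole] = 0.0  # boundary shared by both phases stays a true dip
    return w[:T]


def make_tube_phantom(
    length_vox: int,
    cross_section_vox: int = 4,
    speed_vox_per_frame: float = 1.0,
    n_diastole: int = 8,
    n_systole: int = 8,
    spacing_mm: float = 1.0,
    frame_ms: float = 10.0,
    venc_cm_s: Optional[float] = None,
    modulated: bool = True,
) -> PhantomBundle:
    """Straight-tube phantom with closed-form component ground truth.

    The tube runs along the grid's third axis with spatially uniform axial
    velocity. The LV segment occupies ``length_vox`` voxels between the
    mitral (entry) and aortic (exit) planes. A seed at depth ``z0`` (mm,
    relative to the entry plane) enters during diastole iff
    ``z0 < n_diastole * speed * spacing`` and exits during systole iff
    ``z0 > (length - n_systole * speed) * spacing``, which determines all
    four components in closed form.

    ``speed_vox_per_frame = 0`` is a permitted degenerate case (everything
    residual volume); the bundle is flagged ``meta["degenerate"]``.

    With ``modulated=True`` (default) the speed carries a per-phase
    raised-sine time profile that vanishes at the phase boundaries, and the
    flow is gated so the mitral plane carries flux only during diastole and
    the aortic plane only during systole - the flux curves then have a
    detectable IVR dip and an unambiguous aortic systolic peak. Per-phase
    displacement integrals are preserved exactly, so the closed-form truth
    is unchanged apart from the one-voxel end bands that hold still during
    the phase in which they are gated. ``modulated=False`` gives a strictly
    uniform, time-constant field (useful for preprocessing round-trips).
    """
    if length_vox < 2 or cross_section_vox < 1:
        raise ValueError("tube geometry must have length >= 2 and cross-section >= 1")
    if n_diastole < 1 or n_systole < 1:
        raise ValueError("each phase needs at least 1 frame")
    if speed_vox_per_frame < 0:
        raise ValueError("speed must be non-negative")
    if spacing_mm <= 0 or frame_ms <= 0:
        raise ValueError("spacing and frame duration must be positive")

    L, c = int(length_vox), int(cross_section_vox)
    nd, ns = int(n_diastole), int(n_systole)
    T = nd + ns
    speed = float(speed_vox_per_frame)

    pad = 3  # gap ring (1) + static shell (2)
    nx = ny = c + 2 * pad
    z_off = int(np.ceil(nd * speed)) + 2
    nz = z_off + L + int(np.ceil(speed)) + 2
    core = slice(pad, pad + c)

    speed_cm_s = speed * spacing_mm * 100.0 / frame_ms
    # a modulated profile must vanish at both phase boundaries yet still
    # carry flow, which needs at least two frames per phase
    gated = bool(modulated) and speed > 0 and nd >= 2 and ns >= 2
    w = _tube_speed_profile(nd, ns, gated)
    values = np.zeros((T, nx, ny, nz, 3))
    for t in range(T):
        if gated:
            # diastole: flow everywhere below the aortic end (mitral inflow
            # only); systole: flow everywhere above the mitral end (aortic
            # outflow only). The speed profile vanishes at both phase
            # boundaries, so the time-interpolated field stays piecewise
            # linear in time and RK4 displacement integrals remain exact.
            z_active = slice(0, z_off + L - 1) if t <= nd else slice(z_off + 1, nz)
        else:
            z_active = slice(None)
        values[t, core, core, z_active, 2] = speed_cm_s * w[t]

    if venc_cm_s is None:
        venc_cm_s = max(150.0, 1.2 * speed_cm_s * (w.max() if w.size else 1.0))
    field = VelocityField4D(values, [spacing_mm] * 3, frame_ms, venc_cm_s)

    xi = np.arange(nx)
    shell = (xi < 2) | (xi >= nx - 2)
    static = np.zeros((nx, ny, nz), dtype=bool)
    static[shell, :, :] = True
    static[:, shell, :] = True

    lv = np.zeros((T, nx, ny, nz), dtype=bool)
    lv[:, core, core, z_off : z_off + L] = True

    center = _cross_section_center_mm(nx, spacing_mm)
    radius = (c / 2.0 * np.sqrt(2.0) + 1.0) * spacing_mm
    mitral = ValvePlane(
        "mitral",
        origin_mm=np.array([center, center, z_off * spacing_mm]),
        normal=np.array([0.0, 0.0, 1.0]),
        orifice_radius_mm=radius,
    )
    aortic = ValvePlane(
        "aortic",
        origin_mm=np.array([center, center, (z_off + L) * spacing_mm]),
        normal=np.array([0.0, 0.0, 1.0]),
        orifice_radius_mm=radius,
    )

    z0 = (np.arange(L) + 0.5) * spacing_mm
    entered = z0 < nd * speed * spacing_mm
    exited = z0 > (L - ns * speed) * spacing_mm
    if gated:
        # seeds inside the phase-gated end bands hold still in that phase
        entered &= np.arange(L) < L - 1
        exited &= np.arange(L) >= 1
    per_column = c * c
    voxvol = spacing_mm**3 / 1000.0
    truth = GroundTruth.from_counts(
        int((entered & exited).sum()) * per_column,
        int((entered & ~exited).sum()) * per_column,
        int((~entered & exited).sum()) * per_column,
        int((~entered & ~exited).sum()) * per_column,
        voxvol,
        provenance="analytic",
    )
    phases = PhaseMap(t_ivr=0, t_ed=nd, t_es=0, n_frames=T)
    meta = {
        "kind": "tube",
        "length_vox": L,
        "cross_section_vox": c,
        "speed_vox_per_frame": speed,
        "n_diastole": nd,
        "n_systole": ns,
        "degenerate": speed == 0.0,
        "gated": gated,
        "z_offset_vox": z_off,
    }
    return PhantomBundle(field, lv, static, mitral, aortic, truth, phases, meta)


# ---------------------------------------------------------------------------
# rotation phantom
# ---------------------------------------------------------------------------


def make_rotation_phantom(
    radius_vox: int,
    omega_rad_per_frame: float,
    n_frames: int,
    spacing_mm: float = 1.0,
    frame_ms: float = 20.0,
) -> PhantomBundle:
    """Solid-body rotation about the chamber axis: all residual volume.

    The in-plane velocity is exactly linear in space, so trilinear sampling
    reproduces it without interpolation error and traced orbits are true
    circles - the phantom serves as the integrator-accuracy oracle
    (``omega * n_frames = 2*pi`` returns every particle to its seed).
    """
    if not np.isfinite(omega_rad_per_frame):
        raise ValueError("omega must be finite")
    if n_frames < 2 or radius_vox < 1:
        raise ValueError("need n_frames >= 2 and radius >= 1")

    R = int(radius_vox)
    n = 2 * (R + 4)
    nz = 8
    cx = cy = _cross_section_center_mm(n, spacing_mm)
    x = (np.arange(n) + 0.5) * spacing_mm
    X, Y = np.meshgrid(x, x, indexing="ij")
    r = np.hypot(X - cx, Y - cy)
    moving = r <= (R + 2) * spacing_mm

    vx = np.where(moving, -omega_rad_per_frame * (Y - cy), 0.0)
    vy = np.where(moving, omega_rad_per_frame * (X - cx), 0.0)
    to_cm_s = 100.0 / frame_ms
    values = np.zeros((n_frames, n, n, nz, 3))
    values[..., 0] = (vx * to_cm_s)[None, :, :, None]
    values[..., 1] = (vy * to_cm_s)[None, :, :, None]

    vmax = abs(omega_rad_per_frame) * (R + 2) * spacing_mm * to_cm_s
    venc = max(10.0, 1.3 * vmax)
    field = VelocityField4D(values, [spacing_mm] * 3, frame_ms, venc)

    static = np.broadcast_to((r >= (R + 3.4) * spacing_mm)[:, :, None], (n, n, nz)).copy()
    lv = np.zeros((n_frames, n, n, nz), dtype=bool)
    lv[:, :, :, 2 : nz - 2] = (r <= R * spacing_mm)[None, :, :, None]

    plane_r = (R + 1) * spacing_mm
    mitral = ValvePlane(
        "mitral", np.array([cx, cy, 2 * spacing_mm]), np.array([0.0, 0.0, 1.0]), plane_r
    )
    aortic = ValvePlane(
        "aortic", np.array([cx, cy, (nz - 2) * spacing_mm]), np.array([0.0, 0.0, 1.0]), plane_r
    )
    n_seeds = int(lv[0].sum())
    truth = GroundTruth.from_counts(
        0, 0, 0, n_seeds, spacing_mm**3 / 1000.0, provenance="analytic"
    )
    phases = PhaseMap(t_ivr=0, t_ed=n_frames // 2, t_es=0, n_frames=n_frames)
    meta = {"kind": "rotation", "radius_vox": R, "omega_rad_per_frame": omega_rad_per_frame}
    return PhantomBundle(field, lv, static, mitral, aortic, truth, phases, meta)


# ---------------------------------------------------------------------------
# LV phantom
# ---------------------------------------------------------------------------


def _half_ellipsoid_mask(
    grid_shape: tuple[int, int, int],
    spacing: float,
    center_xy: tuple[float, float],
    z_base: float,
    a: float,
    c: float,
) -> np.ndarray:
    nx, ny, nz = grid_shape
    xs = (np.arange(nx) + 0.5) * spacing
    ys = (np.arange(ny) + 0.5) * spacing
    zs = (np.arange(nz) + 0.5) * spacing
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    inside = (
        ((X - center_xy[0]) / a) ** 2
        + ((Y - center_xy[1]) / a) ** 2
        + ((Z - z_base) / c) ** 2
    ) <= 1.0
    return inside & (Z <= z_base)


def _potential_flow(
    mask: np.ndarray,
    orifice: np.ndarray,
    q_mm3_per_frame: float,
    spacing: float,
) -> np.ndarray:
    """Velocity (mm/frame) from a discrete Neumann Poisson solve on ``mask``.

    The divergence target is a uniform compensation term (the chamber's
    volume change spread over all voxels) plus a concentrated source/sink on
    the orifice voxels carrying the transvalvular flux, which makes the
    discrete problem compatible (zero total divergence) under zero-flux
    walls.
    """
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty chamber mask")
    idx = -np.ones(mask.shape, dtype=np.int64)
    idx[mask] = np.arange(n)

    rows, cols = [], []
    deg = np.zeros(n)
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        pair = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        ia = idx[tuple(sl_a)][pair]
        ib = idx[tuple(sl_b)][pair]
        rows.extend([ia, ib])
        cols.extend([ib, ia])
        np.add.at(deg, ia, 1.0)
        np.add.at(deg, ib, 1.0)
    rows = np.concatenate(rows) if rows else np.array([], dtype=np.int64)
    cols = np.concatenate(cols) if cols else np.array([], dtype=np.int64)
    data = np.ones(rows.size)
    A = sparse.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    A = A - sparse.diags(deg)
    # A phi = h^2 f ; f = uniform sink + orifice source (1/frame units)
    h = spacing
    f = np.full(n, -q_mm3_per_frame / (n * h**3))
    orif_idx = idx[orifice & mask]
    if orif_idx.size == 0:
        raise ValueError("no orifice voxels inside the chamber: geometry not realizable")
    f[orif_idx] += q_mm3_per_frame / (orif_idx.size * h**3)
    b = h**2 * f
    b -= b.mean()  # pure-Neumann compatibility
    phi, info = cg(-A, -b, rtol=1e-9, maxiter=5000)
    if info != 0:
        raise RuntimeError(f"potential solve did not converge (cg info={info})")

    # cell-centred gradient with one-sided differences at the wall
    phi_vol = np.zeros(mask.shape)
    phi_vol[mask] = phi
    u = np.zeros(mask.shape + (3,))
    for axis in range(3):
        fwd = np.zeros(mask.shape, dtype=bool)
        bwd = np.zeros(mask.shape, dtype=bool)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        fwd[tuple(sl_lo)] = mask[tuple(sl_lo)] & mask[tuple(sl_hi)]
        bwd[tuple(sl_hi)] = fwd[tuple(sl_lo)]
        shift_up = np.roll(phi_vol, -1, axis=axis)
        shift_dn = np.roll(phi_vol, 1, axis=axis)
        both = fwd & bwd
        only_f = fwd & ~bwd
        only_b = bwd & ~fwd
        g = np.zeros(mask.shape)
        g[both] = (shift_up[both] - shift_dn[both]) / (2 * h)
        g[only_f] = (shift_up[only_f] - phi_vol[only_f]) / h
        g[only_b] = (phi_vol[only_b] - shift_dn[only_b]) / h
        u[..., axis] = np.where(mask, g, 0.0)
    return u


def _dense_component_oracle(
    field: VelocityField4D,
    seeds: np.ndarray,
    phases: PhaseMap,
    mitral: ValvePlane,
    aortic: ValvePlane,
    substeps: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Entered/exited flags by dense first-order Euler advection.

    Deliberately simple and separate from the RK4 tracer: forward Euler at
    ``substeps`` per frame with independent crossing bookkeeping, used to
    establish ground truth for the LV phantom before the main pipeline ever
    runs on it.
    """
    mm = field.frame_ms / 100.0

    def advect(t0: float, t1: float, plane: ValvePlane) -> np.ndarray:
        n_steps = int(round(abs(t1 - t0) * substeps))
        h = (t1 - t0) / n_steps if n_steps else 0.0
        pos = seeds.copy()
        active = np.ones(len(seeds), dtype=bool)
        crossed = np.zeros(len(seeds), dtype=bool)
        o, nrm = plane.at_frame(0)
        r = plane.orifice_radius_mm
        for k in range(n_steps):
            if not active.any():
                break
            t = t0 + k * h
            act_idx = np.nonzero(active)[0]
            p = pos[act_idx]
            v = sample_velocity(field, p, t) * mm
            p_new = p + h * v
            d0 = (p - o) @ nrm
            d1 = (p_new - o) @ nrm
            hit = (d0 * d1 < 0) | ((d1 == 0) & (d0 != 0))
            frozen = np.zeros(p.shape[0], dtype=bool)
            if np.any(hit):
                s = d0[hit] / (d0[hit] - d1[hit])
                pts = p[hit] + s[:, None] * (p_new[hit] - p[hit])
                rel = pts - o
                inplane = rel - np.outer(rel @ nrm, nrm)
                inside = np.linalg.norm(inplane, axis=1) <= r
                frozen[np.nonzero(hit)[0][inside]] = True
                crossed[act_idx[frozen]] = True
                active[act_idx[frozen]] = False
            pos[act_idx[~frozen]] = p_new[~frozen]
        return crossed

    t_ed = phases.t_ed
    entered = advect(t_ed, t_ed - phases.diastole_frames, mitral)
    exited = advect(t_ed, t_ed + phases.systole_frames, aortic)
    return entered, exited


def make_lv_phantom(
    ed_volume_ml: float = 160.0,
    es_volume_ml: float = 62.0,
    n_frames: int = 20,
    spacing_mm: float = 2.0,
    rng_seed: int = 0,
    aspect: float = 2.6,
    diastole_fraction: float = 0.55,
    rr_ms: float = 900.0,
    oracle_substeps: int = 100,
) -> PhantomBundle:
    """Half-ellipsoid LV phantom with dense-oracle ground truth.

    The chamber is a half-ellipsoid (base plane up, apex down) whose volume
    follows a raised-cosine filling/ejection curve between ``es_volume_ml``
    and ``ed_volume_ml``. Default scales follow healthy-adult chamber
    volumetrics (EDV ~160 ml, ESV ~62 ml). Per frame, the interior velocity
    solves a discrete potential-flow problem whose divergence matches the
    volume-curve rate, with flux carried by a mitral orifice during diastole
    and an aortic orifice during systole. Ground truth (provenance
    ``"dense-oracle"``) comes from dense Euler advection at
    ``oracle_substeps`` per frame, computed at build time.

    The construction is deterministic; ``rng_seed`` is recorded for
    provenance and reserved for optional stochastic extensions.
    """
    if not ed_volume_ml > es_volume_ml > 0:
        raise ValueError("need ed_volume_ml > es_volume_ml > 0")
    if n_frames < 6:
        raise ValueError("need at least 6 frames")

    T = int(n_frames)
    n_d = int(round(diastole_fraction * T))
    n_s = T - n_d
    h = float(spacing_mm)
    frame_ms = rr_ms / T

    ed_mm3 = ed_volume_ml * 1000.0
    a_ed = (ed_mm3 / ((2.0 / 3.0) * np.pi * aspect)) ** (1.0 / 3.0)
    c_ed = aspect * a_ed

    margin = 4
    nx = ny = int(np.ceil(2 * a_ed / h)) + 2 * margin
    nz = int(np.ceil(c_ed / h)) + 2 * margin
    cx = cy = nx * h / 2.0
    z_base = (nz - margin) * h

    def volume_ml(t: float) -> float:
        amp = ed_volume_ml - es_volume_ml
        if t <= n_d:
            return es_volume_ml + amp * 0.5 * (1 - np.cos(np.pi * t / n_d))
        return es_volume_ml + amp * 0.5 * (1 + np.cos(np.pi * (t - n_d) / n_s))

    def dvdt_ml(t: float) -> float:
        amp = ed_volume_ml - es_volume_ml
        if t <= n_d:
            return amp * np.pi / (2 * n_d) * np.sin(np.pi * t / n_d)
        return -amp * np.pi / (2 * n_s) * np.sin(np.pi * (t - n_d) / n_s)

    mitral_c = np.array([cx - 0.42 * a_ed, cy])
    aortic_c = np.array([cx + 0.42 * a_ed, cy])
    r_mitral = 0.38 * a_ed
    r_aortic = 0.30 * a_ed

    xs = (np.arange(nx) + 0.5) * h
    ys = (np.arange(ny) + 0.5) * h
    X2, Y2 = np.meshgrid(xs, ys, indexing="ij")
    in_mitral_xy = (X2 - mitral_c[0]) ** 2 + (Y2 - mitral_c[1]) ** 2 <= r_mitral**2
    in_aortic_xy = (X2 - aortic_c[0]) ** 2 + (Y2 - aortic_c[1]) ** 2 <= r_aortic**2

    values = np.zeros((T, nx, ny, nz, 3))
    lv = np.zeros((T, nx, ny, nz), dtype=bool)
    to_cm_s = 100.0 / frame_ms
    for t in range(T):
        v_ml = volume_ml(t)
        s = (v_ml / ed_volume_ml) ** (1.0 / 3.0)
        mask = _half_ellipsoid_mask((nx, ny, nz), h, (cx, cy), z_base, a_ed * s, c_ed * s)
        if not mask.any():
            raise ValueError("volume curve not realizable on this grid")
        lv[t] = mask
        q = dvdt_ml(t) * 1000.0  # mm^3 per frame
        if abs(q) < 1e-9:
            continue
        z_idx = np.nonzero(mask.any(axis=(0, 1)))[0]
        top = z_idx.max()
        orifice = np.zeros_like(mask)
        xy = in_mitral_xy if q > 0 else in_aortic_xy
        orifice[:, :, top] = xy
        orifice[:, :, top - 1] = xy  # two layers to soften the point source
        u = _potential_flow(mask, orifice, q, h)
        values[t] = u * to_cm_s

    vmax = float(np.abs(values).max())
    venc = max(150.0, 1.1 * vmax)
    field = VelocityField4D(values, [h] * 3, frame_ms, venc)

    ed_mask_any = lv.any(axis=0)
    static = np.zeros((nx, ny, nz), dtype=bool)
    static[:2, :, :] = static[-2:, :, :] = True
    static[:, :2, :] = static[:, -2:, :] = True
    static &= ~ed_mask_any

    z_plane = z_base - 2 * h
    mitral = ValvePlane(
        "mitral",
        np.array([mitral_c[0], mitral_c[1], z_plane]),
        np.array([0.0, 0.0, -1.0]),
        r_mitral + 2.0,
    )
    aortic = ValvePlane(
        "aortic",
        np.array([aortic_c[0], aortic_c[1], z_plane]),
        np.array([0.0, 0.0, 1.0]),
        r_aortic + 2.0,
    )
    phases = PhaseMap(t_ivr=0, t_ed=n_d, t_es=0, n_frames=T)

    ii, jj, kk = np.nonzero(lv[n_d])
    seeds = (np.stack([ii, jj, kk], axis=1) + 0.5) * h
    entered, exited = _dense_component_oracle(
        field, seeds, phases, mitral, aortic, oracle_substeps
    )
    voxvol = h**3 / 1000.0
    truth = GroundTruth.from_counts(
        int((entered & exited).sum()),
        int((entered & ~exited).sum()),
        int((~entered & exited).sum()),
        int((~entered & ~exited).sum()),
        voxvol,
        provenance="dense-oracle",
    )
    meta = {
        "kind": "lv",
        "ed_volume_ml": ed_volume_ml,
        "es_volume_ml": es_volume_ml,
        "rng_seed": rng_seed,
        "a_ed_mm": a_ed,
        "c_ed_mm": c_ed,
        "oracle_substeps": oracle_substeps,
    }
    return PhantomBundle(field, lv, static, mitral, aortic, truth, phases, meta)


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------


@dataclass
class CorruptionSpec:
    """Acquisition-artifact model: polynomial offset, noise, VENC wrap.

    ``offset_coeffs`` has shape (3, K) in cm/s per mm^k with the monomial
    ordering of :func:`ventriflow.preprocess.monomial_exponents`; the
    polynomial order is inferred from K.
    """

    offset_coeffs: np.ndarray
    venc_cm_s: float
    noise_sd_cm_s: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.offset_coeffs = np.atleast_2d(np.asarray(self.offset_coeffs, float))
        if self.venc_cm_s <= 0:
            raise ValueError("venc must be positive")
        if self.noise_sd_cm_s < 0:
            raise ValueError("noise_sd must be non-negative")
        k = self.offset_coeffs.shape[1]
        for order in range(4):
            if len(monomial_exponents(order)) == k:
                self.order = order
                return
        raise ValueError(f"coefficient count {k} matches no polynomial order 0..3")


def corrupt_field(bundle: PhantomBundle, spec: CorruptionSpec) -> VelocityField4D:
    """Apply offset + noise + single phase wrap to a phantom's clean field.

    The wrap maps every value v to ``((v + venc) mod 2 venc) - venc``. At
    most one wrap is permitted: inputs must satisfy ``|v| < 3 venc`` after
    offset and noise (multi-wrap corruption is outside the model).
    """
    field = bundle.field
    cx, cy, cz = field.voxel_centers_mm()
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
    offset = np.zeros(field.grid_shape + (3,))
    for m, (i, j, k) in enumerate(monomial_exponents(spec.order)):
        mono = X**i * Y**j * Z**k
        offset += mono[..., None] * spec.offset_coeffs[:, m]

    v = field.values + offset[None]
    if spec.noise_sd_cm_s > 0:
        rng = np.random.default_rng(spec.rng_seed)
        v = v + rng.normal(0.0, spec.noise_sd_cm_s, size=v.shape)
    if np.abs(v).max() >= 3 * spec.venc_cm_s:
        raise ValueError("corrupted speeds reach 3*venc: would need multi-wrap aliasing")
    wrapped = ((v + spec.venc_cm_s) % (2 * spec.venc_cm_s)) - spec.venc_cm_s
    out = field.with_values(wrapped)
    out.venc_cm_s = spec.venc_cm_s
    return out


# ---------------------------------------------------------------------------
# synthetic cohorts
# ---------------------------------------------------------------------------

#: study-condition moments for the two groups (fractions in %, demographics
#: as printed summary statistics; medians/IQRs converted to normal moments)
CONTROL_GROUP = {
    "fraction_means": (50.0, 23.5, 18.6, 8.0),
    "fraction_sds": (12.2, 5.8, 5.7, 3.8),
    "volume_means_ml": (37.4, 18.1, 15.0, 6.6),
    "n": 30,
    "demo": {
        "age_mean": 50.0,
        "age_sd": 8.0,
        "female_frac": 10 / 30,
        "height_median_m": 1.75,
        "height_iqr_m": (1.67, 1.79),
        "weight_median_kg": 76.0,
        "weight_iqr_kg": (61.0, 82.2),
    },
}
PAF_GROUP = {
    "fraction_means": (44.5, 25.3, 21.6, 8.7),
    "fraction_sds": (11.2, 5.5, 5.6, 4.1),
    "volume_means_ml": (33.5, 19.8, 16.5, 7.4),
    "n": 50,
    "demo": {
        "age_mean": 56.0,
        "age_sd": 12.0,
        "female_frac": 16 / 50,
        "height_median_m": 1.77,
        "height_iqr_m": (1.70, 1.86),
        "weight_median_kg": 81.5,
        "weight_iqr_kg": (72.8, 100.0),
    },
}

IQR_TO_SD = 1.349  # width of the central 50% of a normal in units of sigma


def _iqr_sd(iqr: tuple[float, float]) -> float:
    return (iqr[1] - iqr[0]) / IQR_TO_SD


def make_synthetic_cohort(
    group_means,
    group_sds,
    n: int,
    demo_params: Optional[dict] = None,
    rng_seed: int = 0,
    group_label: str = "control",
) -> pd.DataFrame:
    """Draw one group of per-subject flow-fraction and demographic records.

    Fractions are drawn from an independent multivariate normal matched to
    the given means and SDs, truncated at zero, then renormalized to sum to
    exactly 100 per subject. Demographics use normal draws (median/IQR
    summaries converted via IQR/1.349); body-surface area is computed from
    the drawn height and weight with the Du Bois formula so the usual
    height-weight-BSA dependence structure is present.
    """
    from .anatomy import bsa_du_bois

    means = np.asarray(group_means, dtype=np.float64)
    sds = np.asarray(group_sds, dtype=np.float64)
    if means.shape != (4,) or sds.shape != (4,):
        raise ValueError("group_means and group_sds must be four-vectors")
    if abs(means.sum() - 100.0) > 2.0:
        raise ValueError(f"fraction means sum to {means.sum()}, expected ~100")
    if n < 2:
        raise ValueError("need n >= 2")

    p_neg = float(np.sum(stats.norm.cdf(0.0, loc=means, scale=np.where(sds > 0, sds, 1e-12))))
    if p_neg > 0.01:
        warnings.warn(
            f"fraction moments imply negative draws at rate {p_neg:.3f} (> 1%); "
            "values are truncated at zero before renormalization",
            UserWarning,
            stacklevel=2,
        )

    rng = np.random.default_rng(rng_seed)
    frac = rng.normal(means, sds, size=(n, 4))
    frac = np.clip(frac, 0.0, None)
    frac *= 100.0 / frac.sum(axis=1, keepdims=True)

    demo = dict(demo_params or CONTROL_GROUP["demo"])
    age = rng.normal(demo["age_mean"], demo["age_sd"], n)
    sex = np.where(rng.random(n) < demo["female_frac"], "F", "M")
    height = rng.normal(demo["height_median_m"], _iqr_sd(demo["height_iqr_m"]), n)
    height = np.clip(height, 1.40, 2.10)
    weight = rng.normal(demo["weight_median_kg"], _iqr_sd(demo["weight_iqr_kg"]), n)
    weight = np.clip(weight, 40.0, 160.0)
    bsa = np.array([bsa_du_bois(hh, ww) for hh, ww in zip(height, weight)])

    # mapped end-diastolic volume scale for component volumes (ml)
    total_ml = np.clip(rng.normal(77.0, 15.0, n), 30.0, None)
    return pd.DataFrame(
        {
            "subject_id": [f"{group_label}_{i:03d}" for i in range(n)],
            "group": group_label,
            "age_years": np.round(age, 1),
            "sex": sex,
            "height_m": np.round(height, 3),
            "weight_kg": np.round(weight, 1),
            "bsa_m2": np.round(bsa, 3),
            "df_pct": frac[:, 0],
            "ri_pct": frac[:, 1],
            "de_pct": frac[:, 2],
            "rv_pct": frac[:, 3],
            "df_ml": frac[:, 0] / 100.0 * total_ml,
            "ri_ml": frac[:, 1] / 100.0 * total_ml,
            "de_ml": frac[:, 2] / 100.0 * total_ml,
            "rv_ml": frac[:, 3] / 100.0 * total_ml,
        }
    )


def make_two_group_cohort(
    n_control: int = 30, n_paf: int = 50, rng_seed: int = 0
) -> pd.DataFrame:
    """Control + PAF cohort at the study-condition group moments."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        ctrl = make_synthetic_cohort(
            CONTROL_GROUP["fraction_means"],
            CONTROL_GROUP["fraction_sds"],
            n_control,
            demo_params=CONTROL_GROUP["demo"],
            rng_seed=rng_seed,
            group_label="control",
        )
        paf = make_synthetic_cohort(
            PAF_GROUP["fraction_means"],
            PAF_GROUP["fraction_sds"],
            n_paf,
            demo_params=PAF_GROUP["demo"],
            rng_seed=rng_seed + 1,
            group_label="PAF",
        )
    return pd.concat([ctrl, paf], ignore_index=True)
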