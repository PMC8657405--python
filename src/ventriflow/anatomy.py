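"""Valve planes, transvalvular flux, cardiac-phase detection and volumetrics.

The mitral and aortic valve planes are represented as oriented planes with a
bounded orifice (disc or planar polygon), optionally varying per frame. The
same geometric object is used both for flux integration here and for
pathline crossing tests, so transvalvular flow and component classification
are mutually consistent.

Sign conventions: the mitral normal points LV-inward and the aortic normal
LV-outward, so physiological flow gives positive mitral flux during diastole
and positive aortic flux during systole.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import shapely

from .field import VelocityField4D
from .interpolate import sample_velocity

__all__ = [
    "ValvePlane",
    "PhaseMap",
    "VolumetricsRecord",
    "PhaseDetectionError",
    "transvalvular_flow",
    "detect_phases",
    "lv_volumetrics",
    "la_volume_biplane",
    "bsa_du_bois",
]


class PhaseDetectionError(RuntimeError):
    """Raised when flux curves carry no identifiable systolic peak."""


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane basis for a unit normal."""
    n = np.asarray(normal, dtype=np.float64)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


@dataclass
class ValvePlane:
    """Oriented valve plane with a bounded orifice.

    ``origin_mm`` and ``normal`` may be single vectors (static plane) or
    per-frame ``(n_frames, 3)`` arrays. The orifice is either a disc of
    radius ``orifice_radius_mm`` centred on the origin, or a planar polygon
    given in the plane's deterministic 2-D basis (mm).
    """

    label: str
    origin_mm: np.ndarray
    normal: np.ndarray
    orifice_radius_mm: Optional[float] = None
    orifice_polygon_mm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64)
        self.normal = np.asarray(self.normal, dtype=np.float64)
        norms = np.linalg.norm(self.normal, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError(f"{self.label}: normal must have unit length every frame")
        if (self.orifice_radius_mm is None) == (self.orifice_polygon_mm is None):
            raise ValueError("exactly one of disc radius or polygon must be given")
        if self.orifice_radius_mm is not None and self.orifice_radius_mm <= 0:
            raise ValueError("orifice area must be positive")
        if self.orifice_polygon_mm is not None:
            self.orifice_polygon_mm = np.asarray(self.orifice_polygon_mm, float)
            if self._polygon().area <= 0:
                raise ValueError("orifice area must be positive")

    def _polygon(self) -> "shapely.Polygon":
        return shapely.Polygon(self.orifice_polygon_mm)

    def at_frame(self, frame: int) -> tuple[np.ndarray, np.ndarray]:
        """(origin, normal) of the plane at an integer frame."""
        o = self.origin_mm if self.origin_mm.ndim == 1 else self.origin_mm[frame]
        n = self.normal if self.normal.ndim == 1 else self.normal[frame]
        return o, n

    def orifice_area_mm2(self) -> float:
        if self.orifice_radius_mm is not None:
            return float(np.pi * self.orifice_radius_mm**2)
        return float(self._polygon().area)

    def contains(self, points_mm: np.ndarray, frame: int) -> np.ndarray:
        """Which 3-D points (assumed on the plane) lie inside the orifice."""
        o, n = self.at_frame(frame)
        rel = np.atleast_2d(points_mm) - o
        if self.orifice_radius_mm is not None:
            in_plane = rel - np.outer(rel @ n, n)
            return np.linalg.norm(in_plane, axis=1) <= self.orifice_radius_mm
        e1, e2 = _plane_basis(n)
        return shapely.contains_xy(self._polygon(), rel @ e1, rel @ e2)


@dataclass
class PhaseMap:
    """Key frames of the cycle: diastole onset (IVR), end-diastole, end-systole.

    Under cyclicity end-systole coincides with the next cycle's IVR frame.
    """

    t_ivr: int
    t_ed: int
    t_es: int
    n_frames: int

    def __post_init__(self) -> None:
        for name in ("t_ivr", "t_ed", "t_es"):
            v = getattr(self, name)
            if not (0 <= v < self.n_frames):
                raise ValueError(f"{name}={v} outside [0, {self.n_frames})")

    @property
    def diastole_frames(self) -> int:
        return (self.t_ed - self.t_ivr) % self.n_frames

    @property
    def systole_frames(self) -> int:
        return (self.t_es - self.t_ed) % self.n_frames


def transvalvular_flow(
    field: VelocityField4D,
    plane: ValvePlane,
    frame: float,
    lattice_mm: float = 1.0,
) -> float:
    """Flow rate through a valve orifice in ml/s.

    The surface integral of velocity . normal is evaluated on a regular
    in-plane lattice (default 1 mm, below the stated acquisition
    resolution) with trilinear velocity sampling; the mean normal velocity
    over in-orifice lattice points is multiplied by the exact orifice area.
    Positive values follow the plane normal.
    """
    o, n = plane.at_frame(int(round(frame)) % field.n_frames)
    e1, e2 = _plane_basis(n)
    if plane.orifice_radius_mm is not None:
        half = plane.orifice_radius_mm
        lo1 = lo2 = -half
        hi1 = hi2 = half
    else:
        poly = plane.orifice_polygon_mm
        lo1, lo2 = poly.min(axis=0)
        hi1, hi2 = poly.max(axis=0)
    a = np.arange(lo1 + lattice_mm / 2, hi1, lattice_mm)
    b = np.arange(lo2 + lattice_mm / 2, hi2, lattice_mm)
    A, B = np.meshgrid(a, b, indexing="ij")
    pts = o + A.ravel()[:, None] * e1 + B.ravel()[:, None] * e2
    inside = plane.contains(pts, int(round(frame)) % field.n_frames)
    pts = pts[inside]
    if pts.shape[0] == 0:
        raise ValueError(f"{plane.label}: orifice lattice is empty")
    extent = field.extent_mm
    if np.any(pts < -lattice_mm) or np.any(pts > extent + lattice_mm):
        raise ValueError(f"{plane.label}: orifice lies outside the grid")
    v = sample_velocity(field, pts, frame)  # cm/s
    v_mm_s = (v @ n) * 10.0
    q_mm3_s = float(np.mean(v_mm_s)) * plane.orifice_area_mm2()
    return q_mm3_s / 1000.0


def flux_curves(
    field: VelocityField4D,
    mitral: ValvePlane,
    aortic: ValvePlane,
    lattice_mm: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame mitral and aortic flow-rate series (ml/s)."""
    q_m = np.array(
        [transvalvular_flow(field, mitral, f, lattice_mm) for f in range(field.n_frames)]
    )
    q_a = np.array(
        [transvalvular_flow(field, aortic, f, lattice_mm) for f in range(field.n_frames)]
    )
    return q_m, q_a


def detect_phases(
    q_mitral: Sequence[float],
    q_aortic: Sequence[float],
    lv_volume: Optional[Sequence[float]] = None,
    onset_fraction: float = 0.1,
) -> PhaseMap:
    """Locate IVR (diastole onset), end-diastole and end-systole.

    The IVR frame is the frame after the aortic systolic peak at which the
    combined transvalvular transport ``|q_mitral| + |q_aortic|`` is minimal,
    searching cyclically up to mitral-flow onset; ties break toward the
    earlier frame. End-diastole comes from the LV volume maximum when a
    time-resolved volume series is available, otherwise from the last
    diastolic frame whose mitral flow still exceeds ``onset_fraction`` of
    its peak. End-systole equals the IVR frame under cyclicity.
    """
    q_m = np.asarray(q_mitral, dtype=np.float64)
    q_a = np.asarray(q_aortic, dtype=np.float64)
    T = q_m.size
    if q_a.size != T or T < 4:
        raise ValueError("flux series must share a length of at least 4 frames")
    if np.ptp(q_a) == 0 or q_a.max() <= 0:
        raise PhaseDetectionError("no aortic systolic peak in a flat or non-positive series")

    ia = int(np.argmax(q_a))
    thr = onset_fraction * q_m.max()

    # window: frames strictly after the aortic peak, cyclic, up to and
    # including the first frame of *renewed* mitral inflow (the flow must
    # first dip below the onset threshold, so late-systolic mitral flux -
    # e.g. in a straight-tube geometry - does not end the search early)
    window: list[int] = []
    seen_quiet = False
    for step in range(1, T):
        f = (ia + step) % T
        window.append(f)
        if q_m[f] < thr:
            seen_quiet = True
        elif seen_quiet:
            break
    total = np.abs(q_m[window]) + np.abs(q_a[window])
    t_ivr = int(window[int(np.argmin(total))])

    if lv_volume is not None:
        vol = np.asarray(lv_volume, dtype=np.float64)
        if vol.size != T:
            raise ValueError("lv_volume length must match the flux series")
        t_ed = int(np.argmax(vol))
    else:
        # fallback: end of the contiguous mitral inflow wave after IVR -
        # the frame where mitral flow first falls back below the threshold
        # after having last exceeded it
        f = t_ivr
        for _ in range(T):  # skip any quiescent frames at the window start
            if q_m[f] > thr:
                break
            f = (f + 1) % T
        else:
            raise PhaseDetectionError("no mitral inflow found after IVR")
        for _ in range(T):
            nxt = (f + 1) % T
            if q_m[nxt] <= thr:
                break
            f = nxt
        t_ed = (f + 1) % T
    return PhaseMap(t_ivr=t_ivr, t_ed=t_ed, t_es=t_ivr, n_frames=T)


def bsa_du_bois(height_m: float, weight_kg: float) -> float:
    """Du Bois body-surface area in m**2 from height (m) and weight (kg)."""
    if height_m <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return 0.007184 * weight_kg**0.425 * (height_m * 100.0) ** 0.725


def la_volume_biplane(area_2ch_cm2: float, area_4ch_cm2: float, length_cm: float) -> float:
    """Left-atrial volume (ml) by the biplane area-length method.

    V = (8 / 3 pi) * A_2ch * A_4ch / L with areas in cm**2 and the long-axis
    length in cm.
    """
    if area_2ch_cm2 < 0 or area_4ch_cm2 < 0 or length_cm <= 0:
        raise ValueError("areas must be non-negative and length positive")
    return (8.0 / (3.0 * np.pi)) * area_2ch_cm2 * area_4ch_cm2 / length_cm


@dataclass
class VolumetricsRecord:
    """LV (and optionally LA) volumes and function, raw and BSA-indexed."""

    edv_ml: float
    esv_ml: float
    sv_ml: float
    ef_pct: float
    co_l_min: float
    heart_rate_bpm: float
    bsa_m2: Optional[float] = None
    edv_i_ml_m2: Optional[float] = None
    esv_i_ml_m2: Optional[float] = None
    mass_g: Optional[float] = None
    mass_i_g_m2: Optional[float] = None
    la_volume_ml: Optional[float] = None
    la_volume_i_ml_m2: Optional[float] = None
    t_ed: Optional[int] = None
    t_es: Optional[int] = None


def lv_volumetrics(
    lv_mask: np.ndarray,
    spacing_mm: Sequence[float],
    heart_rate_bpm: float,
    height_m: Optional[float] = None,
    weight_kg: Optional[float] = None,
    t_ed: Optional[int] = None,
    t_es: Optional[int] = None,
    mass_g: Optional[float] = None,
    la_volume_ml: Optional[float] = None,
) -> VolumetricsRecord:
    """Chamber volumetrics from per-frame LV masks.

    EDV and ESV are voxel counts times voxel volume at the frames of
    maximal and minimal LV volume (or at explicitly supplied frames);
    SV = EDV - ESV, EF = 100 SV / EDV, CO = SV x HR / 1000. When height and
    weight are given, BSA (Du Bois) and indexed values are filled in.
    """
    mask = np.asarray(lv_mask).astype(bool)
    if mask.ndim != 4:
        raise ValueError("lv_mask must be 4-D (frames, nx, ny, nz)")
    voxvol_ml = float(np.prod(np.asarray(spacing_mm, float))) / 1000.0
    counts = mask.reshape(mask.shape[0], -1).sum(axis=1)
    if np.count_nonzero(counts) < 2:
        raise ValueError("lv_mask must be non-empty at two or more frames")
    vol = counts * voxvol_ml
    if t_ed is None:
        t_ed = int(np.argmax(vol))
    if t_es is None:
        t_es = int(np.argmin(np.where(vol > 0, vol, np.inf)))
    edv, esv = float(vol[t_ed]), float(vol[t_es])
    if edv <= 0:
        raise ValueError("empty LV mask at end-diastole")
    sv = edv - esv
    rec = VolumetricsRecord(
        edv_ml=edv,
        esv_ml=esv,
        sv_ml=sv,
        ef_pct=100.0 * sv / edv,
        co_l_min=sv * heart_rate_bpm / 1000.0,
        heart_rate_bpm=heart_rate_bpm,
        mass_g=mass_g,
        la_volume_ml=la_volume_ml,
        t_ed=t_ed,
        t_es=t_es,
    )
    if height_m is not None and weight_kg is not None:
        bsa = bsa_du_bois(height_m, weight_kg)
        rec.bsa_m2 = bsa
        rec.edv_i_ml_m2 = edv / bsa
        rec.esv_i_ml_m2 = esv / bsa
        if mass_g is not None:
            rec.mass_i_g_m2 = mass_g / bsa
        if la_volume_ml is not None:
            rec.la_volume_i_ml_m2 = la_volume_ml / bsa
    return rec
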