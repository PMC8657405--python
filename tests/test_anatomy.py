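"""Valve-plane flux, phase detection, volumetrics and clinical formulas."""

import numpy as np
import pytest

import ventriflow as vf
from ventriflow.anatomy import (
    PhaseDetectionError,
    ValvePlane,
    bsa_du_bois,
    detect_phases,
    flux_curves,
    la_volume_biplane,
    lv_volumetrics,
    transvalvular_flow,
)
from ventriflow.field import VelocityField4D

DISC_4CM2 = float(np.sqrt(400.0 / np.pi))  # radius of a 4 cm^2 orifice, mm


def uniform_field(vz_cm_s: float, n: int = 30) -> VelocityField4D:
    values = np.zeros((2, n, n, n, 3))
    values[..., 2] = vz_cm_s
    return VelocityField4D(values, [1, 1, 1], 30.0, 150.0)


def test_flux_uniform_flow():
    """Uniform 10 cm/s normal flow through a 4 cm^2 orifice gives 40 ml/s."""
    f = uniform_field(10.0)
    plane = ValvePlane("aortic", [15.0, 15.0, 15.0], [0, 0, 1.0], DISC_4CM2)
    assert transvalvular_flow(f, plane, 0) == pytest.approx(40.0, abs=1e-9)


def test_flux_zero_field():
    f = uniform_field(0.0)
    plane = ValvePlane("aortic", [15.0, 15.0, 15.0], [0, 0, 1.0], DISC_4CM2)
    assert transvalvular_flow(f, plane, 0) == 0.0


def test_flux_tilted_plane_cosine():
    """A plane tilted 60 degrees from the flow axis sees v A cos(60) = half."""
    f = uniform_field(10.0)
    th = np.deg2rad(60.0)
    normal = np.array([np.sin(th), 0.0, np.cos(th)])
    plane = ValvePlane("aortic", [15.0, 15.0, 15.0], normal, DISC_4CM2)
    assert transvalvular_flow(f, plane, 0) == pytest.approx(20.0, abs=1e-9)


def test_flux_linearity_in_field():
    rng = np.random.default_rng(9)
    v1 = rng.normal(0, 10, (2, 20, 20, 20, 3))
    v2 = rng.normal(0, 10, (2, 20, 20, 20, 3))
    mk = lambda v: VelocityField4D(v, [1, 1, 1], 30.0, 150.0)
    plane = ValvePlane("mitral", [10.0, 10.0, 10.0], [0, 0, 1.0], 5.0)
    q1 = transvalvular_flow(mk(v1), plane, 1)
    q2 = transvalvular_flow(mk(v2), plane, 1)
    q12 = transvalvular_flow(mk(2.0 * v1 + 0.5 * v2), plane, 1)
    assert q12 == pytest.approx(2.0 * q1 + 0.5 * q2, rel=1e-9)


def test_flux_orifice_outside_grid():
    f = uniform_field(10.0, n=10)
    plane = ValvePlane("aortic", [50.0, 50.0, 5.0], [0, 0, 1.0], 5.0)
    with pytest.raises(ValueError, match="outside the grid"):
        transvalvular_flow(f, plane, 0)


def test_polygon_orifice_matches_disc():
    """A finely sampled polygonal approximation of the disc gives nearly the
    same flux as the disc itself."""
    f = uniform_field(10.0)
    ang = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    poly = DISC_4CM2 * np.stack([np.cos(ang), np.sin(ang)], axis=1)
    disc = ValvePlane("aortic", [15.0, 15.0, 15.0], [0, 0, 1.0], DISC_4CM2)
    pgon = ValvePlane("aortic", [15.0, 15.0, 15.0], [0, 0, 1.0], None, poly)
    qd = transvalvular_flow(f, disc, 0)
    qp = transvalvular_flow(f, pgon, 0)
    assert qp == pytest.approx(qd, rel=5e-3)


def test_tube_mass_balance(tube_88):
    """Time-integrated mitral inflow equals aortic outflow within 1%."""
    qm, qa = flux_curves(tube_88.field, tube_88.mitral, tube_88.aortic)
    inflow, outflow = qm.sum(), qa.sum()
    assert inflow > 0
    assert abs(inflow - outflow) / max(inflow, outflow) < 0.01


# -- phase detection ---------------------------------------------------------


def constructed_series():
    T = 20
    qa = np.zeros(T)
    qa[4:12] = [50, 120, 200, 250, 180, 60, 4, 1]
    qm = np.zeros(T)
    qm[10:12] = [5, 2]
    qm[12:18] = [80, 150, 100, 40, 90, 30]
    return qm, qa


def test_detect_phases_constructed_series():
    qm, qa = constructed_series()
    pm = detect_phases(qm, qa)
    assert pm.t_ivr == 11  # combined flux minimal after the frame-7 aortic peak
    assert pm.t_es == pm.t_ivr


def test_detect_phases_tube_matches_construction(tube_88, tube_55):
    for b in (tube_88, tube_55):
        qm, qa = flux_curves(b.field, b.mitral, b.aortic)
        pm = detect_phases(qm, qa)
        assert pm.t_ivr == b.phases.t_ivr
        assert pm.t_ed == b.phases.t_ed


def test_detect_phases_volume_argmax():
    qm, qa = constructed_series()
    vol = np.concatenate([np.linspace(60, 160, 15), np.linspace(160, 60, 5)])
    assert detect_phases(qm, qa, vol).t_ed == 14


def test_detect_phases_cyclic_shift_equivariance():
    qm, qa = constructed_series()
    pm0 = detect_phases(qm, qa)
    for k in (3, 9):
        pm = detect_phases(np.roll(qm, k), np.roll(qa, k))
        assert pm.t_ivr == (pm0.t_ivr + k) % qm.size
        assert pm.t_ed == (pm0.t_ed + k) % qm.size


def test_detect_phases_flat_series_fails():
    with pytest.raises(PhaseDetectionError):
        detect_phases(np.zeros(10), np.zeros(10))


# -- volumetrics -------------------------------------------------------------


def make_masks(ed_vox: int, es_vox: int):
    masks = np.zeros((4, 10, 10, 10), bool)
    masks[0].flat[:ed_vox] = True  # frame 0: end-diastole
    masks[1].flat[:es_vox] = True
    masks[2].flat[: (ed_vox + es_vox) // 2] = True
    masks[3].flat[: (ed_vox + es_vox) // 2] = True
    return masks


def test_volumetrics_definitions():
    masks = make_masks(100, 40)  # 1 ml voxels at 10 mm spacing... use 10mm
    rec = lv_volumetrics(masks, [10, 10, 10], heart_rate_bpm=60.0)
    assert rec.edv_ml == pytest.approx(100.0)
    assert rec.esv_ml == pytest.approx(40.0)
    assert rec.sv_ml == pytest.approx(60.0)
    assert rec.ef_pct == pytest.approx(60.0)
    assert rec.co_l_min == pytest.approx(3.6)


def test_cardiac_output():
    masks = make_masks(100, 0)
    masks[1].flat[:1] = True  # avoid empty frame
    rec = lv_volumetrics(masks, [10, 10, 10], heart_rate_bpm=60.0)
    assert rec.sv_ml == pytest.approx(99.0)
    assert rec.co_l_min == pytest.approx(5.94)


def test_bsa_du_bois_against_cohort_medians():
    """Median height 1.77 m and weight 81.5 kg give BSA ~1.99 m^2."""
    assert bsa_du_bois(1.77, 81.5) == pytest.approx(1.99, abs=0.02)


def test_indexed_volumetrics_scale_inversely_with_bsa():
    masks = make_masks(120, 50)
    rng = np.random.default_rng(4)
    for _ in range(5):
        h, w = rng.uniform(1.5, 2.0), rng.uniform(50, 110)
        rec = lv_volumetrics(masks, [10, 10, 10], 70.0, height_m=h, weight_kg=w)
        assert rec.edv_i_ml_m2 * rec.bsa_m2 == pytest.approx(rec.edv_ml, rel=1e-12)
        assert rec.esv_i_ml_m2 * rec.bsa_m2 == pytest.approx(rec.esv_ml, rel=1e-12)


def test_volumetrics_empty_mask_rejected():
    with pytest.raises(ValueError):
        lv_volumetrics(np.zeros((4, 5, 5, 5), bool), [1, 1, 1], 60.0)


def test_la_volume_biplane():
    assert la_volume_biplane(20.0, 20.0, 5.0) == pytest.approx(67.9, abs=0.05)
    assert la_volume_biplane(0.0, 20.0, 5.0) == 0.0
    v1 = la_volume_biplane(18.0, 22.0, 4.0)
    assert la_volume_biplane(18.0, 22.0, 8.0) == pytest.approx(v1 / 2.0)
    with pytest.raises(ValueError):
        la_volume_biplane(20.0, 20.0, 0.0)
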