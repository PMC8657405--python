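"""Phantom generators: ground truth, invariants, corruption, cohorts."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ventriflow as vf
from ventriflow.phantom import CONTROL_GROUP, PAF_GROUP, CorruptionSpec


def bundle_invariants(bundle):
    assert not np.any(bundle.lv_mask & bundle.static_mask[None])
    assert np.all(bundle.field.values[:, bundle.static_mask, :] == 0.0)
    assert abs(bundle.truth.pct_vector().sum() - 100.0) < 1e-9
    total = (bundle.truth.df_ml + bundle.truth.ri_ml + bundle.truth.de_ml
             + bundle.truth.rv_ml)
    assert abs(total - bundle.truth.seeded_volume_ml) < 1e-9


@pytest.mark.parametrize(
    "nd, ns, speed, expected",
    [
        (8, 8, 1.0, (60.0, 20.0, 20.0, 0.0)),
        (5, 5, 1.0, (0.0, 50.0, 50.0, 0.0)),
        (8, 8, 0.0, (0.0, 0.0, 0.0, 100.0)),
    ],
)
def test_tube_truth_closed_form(nd, ns, speed, expected):
    b = vf.make_tube_phantom(10, 4, speed, nd, ns)
    np.testing.assert_allclose(b.truth.pct_vector(), expected, atol=1e-12)
    bundle_invariants(b)
    if speed == 0.0:
        assert b.meta["degenerate"]


@pytest.mark.parametrize("nd, ns, L, speed", [(8, 8, 10, 1.0), (6, 9, 12, 1.0), (4, 3, 8, 2.0)])
def test_tube_truth_matches_brute_force_advection(nd, ns, L, speed):
    """Independent oracle: per-frame dense advection of seed depths along the
    tube axis, sampling the actual stored velocity profile, reproduces the
    closed-form entered/exited decision for every seed."""
    b = vf.make_tube_phantom(L, 2, speed, nd, ns)
    f = b.field
    core = b.lv_mask[0].any(axis=2)
    ci, cj = [int(v[0]) for v in np.nonzero(core)]
    z_off = b.meta["z_offset_vox"]
    spacing = f.spacing_mm[2]
    z_mitral = z_off * spacing
    z_aortic = (z_off + L) * spacing

    def axial_speed(z_mm, t):
        # direct sampling of the stored field on the tube axis (mm/frame)
        pos = np.array([[(ci + 0.5) * f.spacing_mm[0], (cj + 0.5) * f.spacing_mm[1], z_mm]])
        return float(vf.sample_velocity(f, pos, t)[0, 2]) * f.frame_ms / 100.0

    sub = 200
    n_df = n_ri = n_de = n_rv = 0
    for i in range(L):
        z_ed = z_mitral + (i + 0.5) * spacing
        z = z_ed
        entered = False
        for k in range(nd * sub):  # backward through diastole
            z -= axial_speed(z, nd - k / sub) / sub
            if z <= z_mitral:
                entered = True
                break
        z = z_ed
        exited = False
        for k in range(ns * sub):  # forward through systole
            z += axial_speed(z, nd + k / sub) / sub
            if z >= z_aortic:
                exited = True
                break
        n_df += entered and exited
        n_ri += entered and not exited
        n_de += exited and not entered
        n_rv += not entered and not exited
    per_col = int(core.sum())
    counts = np.array([n_df, n_ri, n_de, n_rv]) * per_col
    np.testing.assert_allclose(
        b.truth.pct_vector(), 100.0 * counts / counts.sum(), atol=1e-9
    )


def test_tube_invalid_geometry():
    with pytest.raises(ValueError):
        vf.make_tube_phantom(1, 4, 1.0, 8, 8)
    with pytest.raises(ValueError):
        vf.make_tube_phantom(10, 4, 1.0, 0, 8)
    with pytest.raises(ValueError):
        vf.make_tube_phantom(10, 4, -1.0, 8, 8)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    L=st.integers(4, 10),
    nd=st.integers(1, 8),
    ns=st.integers(1, 7),
    speed=st.sampled_from([0.5, 1.0, 2.0]),
)
def test_tube_truth_properties(L, nd, ns, speed):
    """Truth sums are exact and the ejected share (DF + DE) never decreases
    when systole lengthens."""
    b = vf.make_tube_phantom(L, 2, speed, nd, ns)
    bundle_invariants(b)
    b2 = vf.make_tube_phantom(L, 2, speed, nd, ns + 1)
    assert (b2.truth.df_pct + b2.truth.de_pct) >= (b.truth.df_pct + b.truth.de_pct) - 1e-12


def test_rotation_truth_and_invariants(rotation_cycle):
    np.testing.assert_allclose(rotation_cycle.truth.pct_vector(), [0, 0, 0, 100])
    bundle_invariants(rotation_cycle)


def test_rotation_zero_omega_matches_zero_field():
    b = vf.make_rotation_phantom(6, 0.0, 8)
    assert np.all(b.field.values == 0.0)
    np.testing.assert_allclose(b.truth.pct_vector(), [0, 0, 0, 100])


def test_lv_phantom_truth(lv_coarse):
    bundle_invariants(lv_coarse)
    assert lv_coarse.truth.provenance == "dense-oracle"
    assert lv_coarse.truth.df_pct > 0
    assert lv_coarse.truth.rv_pct > 0


def test_lv_phantom_volume_curve(lv_coarse):
    """The per-frame mask volume follows the filling/ejection curve between
    the end-systolic and end-diastolic targets."""
    voxvol = lv_coarse.field.voxel_volume_ml()
    vols = lv_coarse.lv_mask.reshape(lv_coarse.field.n_frames, -1).sum(1) * voxvol
    t_ed = lv_coarse.phases.t_ed
    assert vols.argmax() == t_ed
    assert abs(vols[t_ed] - 160.0) / 160.0 < 0.10  # voxelization tolerance
    assert abs(vols.min() - 62.0) / 62.0 < 0.15


def test_lv_phantom_no_ejection_limit():
    """As ESV approaches EDV there is no transvalvular transport: direct flow
    and delayed ejection both vanish."""
    b = vf.make_lv_phantom(120.0, 119.5, n_frames=8, spacing_mm=4.0, oracle_substeps=30)
    assert b.truth.df_pct == 0.0
    assert b.truth.de_pct == 0.0


def test_lv_phantom_deterministic():
    a = vf.make_lv_phantom(100.0, 50.0, n_frames=8, spacing_mm=4.0, oracle_substeps=30)
    b = vf.make_lv_phantom(100.0, 50.0, n_frames=8, spacing_mm=4.0, oracle_substeps=30)
    assert np.array_equal(a.field.values, b.field.values)
    assert np.array_equal(a.lv_mask, b.lv_mask)
    assert a.truth == b.truth


def test_lv_phantom_rejects_bad_volumes():
    with pytest.raises(ValueError):
        vf.make_lv_phantom(60.0, 160.0)


# -- corruption --------------------------------------------------------------


def test_corrupt_wrap_arithmetic():
    """A true velocity of 170 cm/s at VENC 150 is stored as -130."""
    b = vf.make_tube_phantom(6, 2, 0.0, 2, 2)
    spec = CorruptionSpec(np.array([[0.0], [0.0], [170.0]]), venc_cm_s=150.0)
    out = vf.corrupt_field(b, spec)
    assert np.allclose(out.values[..., 2], -130.0)
    assert out.venc_cm_s == 150.0


def test_corrupt_identity():
    b = vf.make_tube_phantom(6, 2, 1.0, 3, 3, modulated=False)
    spec = CorruptionSpec(np.zeros((3, 1)), venc_cm_s=1000.0)
    out = vf.corrupt_field(b, spec)
    assert np.array_equal(out.values, b.field.values)


def test_corrupt_offset_on_static_voxels():
    """Static tissue carries exactly the planted polynomial 2 + 0.1x - 0.05y."""
    b = vf.make_tube_phantom(6, 2, 1.0, 3, 3, modulated=False)
    coeffs = np.zeros((3, 4))
    coeffs[2] = [2.0, 0.1, -0.05, 0.0]
    out = vf.corrupt_field(b, CorruptionSpec(coeffs, venc_cm_s=1000.0))
    cx, cy, cz = b.field.voxel_centers_mm()
    ii, jj, kk = np.nonzero(b.static_mask)
    expected = 2.0 + 0.1 * cx[ii] - 0.05 * cy[jj]
    np.testing.assert_allclose(out.values[0][b.static_mask][:, 2], expected, atol=1e-12)


def test_corrupt_rejects_multiwrap():
    b = vf.make_tube_phantom(6, 2, 0.0, 2, 2)
    with pytest.raises(ValueError, match="multi-wrap"):
        vf.corrupt_field(b, CorruptionSpec(np.array([[0.0], [0.0], [500.0]]), venc_cm_s=100.0))


def test_corrupt_noise_seeded():
    b = vf.make_tube_phantom(6, 2, 1.0, 3, 3)
    spec = CorruptionSpec(np.zeros((3, 1)), venc_cm_s=1000.0, noise_sd_cm_s=1.0, rng_seed=11)
    out1 = vf.corrupt_field(b, spec)
    out2 = vf.corrupt_field(b, spec)
    assert np.array_equal(out1.values, out2.values)
    sd = np.std(out1.values - b.field.values)
    assert abs(sd - 1.0) < 0.02


# -- synthetic cohorts -------------------------------------------------------


def test_cohort_moment_recovery_small():
    means, sds = CONTROL_GROUP["fraction_means"], CONTROL_GROUP["fraction_sds"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        tab = vf.make_synthetic_cohort(means, sds, 30, rng_seed=12)
    got = tab[["df_pct", "ri_pct", "de_pct", "rv_pct"]].mean().to_numpy()
    tol = 2 * np.asarray(sds) / np.sqrt(30)
    assert np.all(np.abs(got - np.asarray(means)) < tol + 0.5)


def test_cohort_zero_sds_exact():
    tab = vf.make_synthetic_cohort((50.0, 25.0, 17.0, 8.0), (0, 0, 0, 0), 5, rng_seed=0)
    np.testing.assert_allclose(
        tab[["df_pct", "ri_pct", "de_pct", "rv_pct"]].to_numpy(),
        np.tile([50.0, 25.0, 17.0, 8.0], (5, 1)),
    )


def test_cohort_monte_carlo_mean_recovery():
    means, sds = PAF_GROUP["fraction_means"], PAF_GROUP["fraction_sds"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        tab = vf.make_synthetic_cohort(means, sds, 10_000, rng_seed=5, group_label="PAF")
    got = tab[["df_pct", "ri_pct", "de_pct", "rv_pct"]].mean().to_numpy()
    assert np.all(np.abs(got - np.asarray(means)) < 0.5)


def test_cohort_reproducible_and_normalized():
    a = vf.make_two_group_cohort(rng_seed=3)
    b = vf.make_two_group_cohort(rng_seed=3)
    assert a.equals(b)
    sums = a[["df_pct", "ri_pct", "de_pct", "rv_pct"]].sum(axis=1)
    np.testing.assert_allclose(sums, 100.0, atol=1e-9)


def test_cohort_infeasible_moments_warn():
    with pytest.warns(UserWarning, match="negative draws"):
        vf.make_synthetic_cohort((70.0, 20.0, 7.0, 3.0), (10.0, 5.0, 4.0, 4.0), 10, rng_seed=0)
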