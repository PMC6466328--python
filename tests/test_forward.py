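"""Quasi-static forward model: pose transform, SAR field, metrics."""

import math

import numpy as np
import pytest

from rfdosim.forward import (
    CoilField,
    Pose,
    SARResult,
    compute_sar_result,
    hd_sar,
    normalize_sar,
    pose_transform,
    psar10g,
    sar_field,
    wb_sar,
)
from rfdosim.phantoms import VoxelPhantom

from _oracles import psar10g_bruteforce, random_label_phantom
from conftest import make_property_table


def _phantom(labels, **kw):
    return VoxelPhantom(labels=np.asarray(labels, dtype=np.int16), **kw)


# ---------------------------------------------------------------------------
# Pose transform
# ---------------------------------------------------------------------------


def test_zero_pose_maps_alignment_plane_to_coil_centre(rng):
    labels = rng.integers(0, 2, size=(6, 6, 10)).astype(np.int16)
    # alignment plane at the centre of voxel layer 4 along the long axis
    phantom = _phantom(labels, voxel_size=0.01, alignment_z=(4 + 0.5) * 0.01)
    pos = pose_transform(phantom, Pose(0, 0), table_offset=0.0, z_centre=0.37)
    z = pos[:, 2].reshape(phantom.shape)
    assert np.allclose(z[:, :, 4], 0.37, atol=1e-12)


def test_z_shift_is_a_pure_translation(rng):
    labels = rng.integers(0, 2, size=(5, 7, 9)).astype(np.int16)
    phantom = _phantom(labels)
    base = pose_transform(phantom, Pose(0, 0))
    shifted = pose_transform(phantom, Pose(0.034, 0))
    assert np.allclose(shifted[:, 2] - base[:, 2], 0.034, atol=1e-12)
    assert np.allclose(shifted[:, :2], base[:, :2], atol=1e-15)


def test_tilt_is_a_rigid_rotation_about_the_body_axis(rng):
    labels = rng.integers(0, 2, size=(8, 8, 12)).astype(np.int16)
    phantom = _phantom(labels)
    offset = 0.05
    base = pose_transform(phantom, Pose(0, 0), table_offset=offset)
    rot = pose_transform(phantom, Pose(0, 3.7), table_offset=offset)
    # body axis sits at (0, -table_offset) in the coil frame
    axis = np.array([0.0, -offset])
    d_base = np.linalg.norm(base[:, :2] - axis, axis=1)
    d_rot = np.linalg.norm(rot[:, :2] - axis, axis=1)
    assert np.allclose(d_base, d_rot, atol=1e-12)
    # pairwise distances of a random voxel subset are preserved
    idx = rng.choice(len(base), size=40, replace=False)
    pb = base[idx]
    pr = rot[idx]
    db = np.linalg.norm(pb[:, None, :] - pb[None, :, :], axis=-1)
    dr = np.linalg.norm(pr[:, None, :] - pr[None, :, :], axis=-1)
    assert np.allclose(db, dr, atol=1e-12)


# ---------------------------------------------------------------------------
# SAR field
# ---------------------------------------------------------------------------


def test_lossless_body_has_zero_sar(rng):
    labels = rng.integers(0, 2, size=(6, 6, 6)).astype(np.int16)
    props = make_property_table([0.0], [1000.0])
    sar = sar_field(_phantom(labels), props, CoilField())
    assert np.all(sar == 0.0)


def test_voxel_on_coil_axis_has_zero_sar():
    labels = np.ones((1, 1, 1), dtype=np.int16)
    phantom = _phantom(labels, voxel_size=0.002, alignment_z=0.001)
    props = make_property_table([0.5], [1000.0])
    coil = CoilField(table_offset=0.0)  # body axis on the coil axis
    sar = sar_field(phantom, props, coil)
    assert sar[0, 0, 0] == 0.0


def test_single_voxel_closed_form_value():
    # sigma=0.5 S/m, rho=1000 kg/m^3, d=0.1 m, w=1, f=64 MHz, B1=1 uT
    labels = np.ones((1, 1, 1), dtype=np.int16)
    phantom = _phantom(labels, voxel_size=0.002, alignment_z=0.001)
    props = make_property_table([0.5], [1000.0])
    coil = CoilField(table_offset=0.1)
    sar = sar_field(phantom, props, coil)
    omega = 2 * math.pi * 64e6
    expected = 0.5 * (omega * 1e-6 * 0.1 / 2) ** 2 / (2 * 1000.0)
    assert sar[0, 0, 0] == pytest.approx(expected, rel=1e-12)


def test_axial_profile_plateau_taper_and_cutoff():
    coil = CoilField(length=0.2, taper_length=0.1, z_centre=0.0)
    z = np.array([0.0, 0.09, 0.1, 0.15, 0.2, 0.25])
    w = coil.axial_profile(z)
    assert w[0] == w[1] == w[2] == 1.0
    assert w[3] == pytest.approx(math.cos(math.pi * 0.05 / 0.2) ** 2)
    assert w[4] == pytest.approx(0.0, abs=1e-30)
    assert w[5] == 0.0


# ---------------------------------------------------------------------------
# Mass-averaged metrics
# ---------------------------------------------------------------------------


def test_uniform_sar_averages_to_itself(rng):
    labels = rng.integers(0, 3, size=(6, 6, 6)).astype(np.int16)
    labels[2, 2, 2] = 1  # ensure tissue present
    mask = (labels != 0) & (rng.uniform(size=labels.shape) < 0.5)
    phantom = _phantom(labels, head_mask=mask)
    props = make_property_table([0.3, 0.9], [900.0, 1800.0])
    sar = np.where(labels != 0, 1.7, 0.0)
    assert wb_sar(sar, phantom, props) == pytest.approx(1.7, rel=1e-12)
    if mask.any():
        assert hd_sar(sar, phantom, props) == pytest.approx(1.7, rel=1e-12)


def test_uniform_density_reduces_to_unweighted_mean(rng):
    labels = rng.integers(0, 2, size=(5, 5, 5)).astype(np.int16)
    labels[0, 0, 0] = 1
    phantom = _phantom(labels)
    props = make_property_table([0.4], [1000.0])
    sar = rng.uniform(size=labels.shape) * (labels != 0)
    expected = sar[labels != 0].mean()
    assert wb_sar(sar, phantom, props) == pytest.approx(expected, rel=1e-12)


def test_weighted_mean_matches_summation_oracle(rng):
    labels, sigma, rho = random_label_phantom(rng, (7, 7, 7))
    labels[3, 3, 3] = 1
    phantom = _phantom(labels)
    props = make_property_table(sigma[1:], rho[1:])
    sar = rng.uniform(size=labels.shape) * (labels != 0)
    mass = rho[labels] * phantom.voxel_volume
    tissue = labels != 0
    expected = (sar[tissue] * mass[tissue]).sum() / mass[tissue].sum()
    assert wb_sar(sar, phantom, props) == pytest.approx(expected, rel=1e-12)


def test_empty_head_mask_rejected(rng):
    labels = np.ones((3, 3, 3), dtype=np.int16)
    phantom = _phantom(labels)
    props = make_property_table([0.4], [1000.0])
    with pytest.raises(ValueError, match="empty"):
        hd_sar(np.ones(labels.shape), phantom, props)


# ---------------------------------------------------------------------------
# Peak spatial SAR (10 g cubes)
# ---------------------------------------------------------------------------


def test_psar_uniform_interior_equals_uniform_value():
    labels = np.ones((15, 15, 15), dtype=np.int16)
    phantom = _phantom(labels, voxel_size=0.004)
    props = make_property_table([0.4], [1000.0])
    sar = np.full(labels.shape, 2.5)
    value, _ = psar10g(sar, phantom, props, target_mass=0.010)
    assert value == pytest.approx(2.5, rel=1e-12)


def test_psar_homogeneity_in_field_amplitude(rng):
    labels, sigma, rho = random_label_phantom(rng, (18, 18, 18))
    labels[9, 9, 9] = 1
    phantom = _phantom(labels, voxel_size=0.004)
    props = make_property_table(sigma[1:], rho[1:])
    sar = rng.uniform(size=labels.shape) * (labels != 0)
    v1, loc1 = psar10g(sar, phantom, props, target_mass=0.005)
    v2, loc2 = psar10g(3.0 * sar, phantom, props, target_mass=0.005)
    assert v2 == pytest.approx(3.0 * v1, rel=1e-12)
    assert loc1 == loc2


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_psar_equals_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(16, 25, size=3))
    labels, sigma, rho = random_label_phantom(rng, shape)
    phantom = _phantom(labels, voxel_size=0.004)
    props = make_property_table(sigma[1:], rho[1:])
    sar = rng.uniform(size=shape) * (labels != 0)
    target = float(rng.uniform(0.002, 0.008))
    value, loc = psar10g(sar, phantom, props, target_mass=target)
    exp_value, exp_loc = psar10g_bruteforce(
        sar, labels, phantom.voxel_size, rho, target
    )
    assert value == pytest.approx(exp_value, rel=1e-9)
    assert loc == exp_loc


def test_psar_unreachable_target_rejected():
    labels = np.ones((3, 3, 3), dtype=np.int16)
    phantom = _phantom(labels, voxel_size=0.002)
    props = make_property_table([0.4], [1000.0])
    with pytest.raises(ValueError, match="target mass"):
        psar10g(np.ones(labels.shape), phantom, props, target_mass=10.0)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def test_absorbed_power_normalization_hits_one_watt(rng):
    labels, sigma, rho = random_label_phantom(rng, (6, 6, 6))
    labels[0, 0, 0] = 1
    phantom = _phantom(labels)
    props = make_property_table(sigma[1:], rho[1:])
    sar = rng.uniform(size=labels.shape) * (labels != 0)
    out = normalize_sar(sar, phantom, props, "absorbed_power_1W")
    mass = rho[labels] * phantom.voxel_volume
    assert (out * mass).sum() == pytest.approx(1.0, rel=1e-12)
    # raw mode is the identity
    assert normalize_sar(sar, phantom, props, "raw_B1") is sar


def test_metric_ratios_invariant_under_normalization(coarse_pair, coil):
    phantom, props, _, _ = coarse_pair
    sar = sar_field(phantom, props, coil, Pose(0.02, 1.0))
    norm = normalize_sar(sar, phantom, props, "absorbed_power_1W")
    r_raw = psar10g(sar, phantom, props)[0] / wb_sar(sar, phantom, props)
    r_norm = psar10g(norm, phantom, props)[0] / wb_sar(norm, phantom, props)
    assert r_norm == pytest.approx(r_raw, rel=1e-12)


# ---------------------------------------------------------------------------
# Physical invariants on the synthetic body
# ---------------------------------------------------------------------------


def test_peak_exceeds_whole_body_average(coarse_pair, coil):
    phantom, props, _, _ = coarse_pair
    res = compute_sar_result(phantom, props, coil)
    assert res.psar10g >= res.wbsar
    assert res.wbsar > 0 and res.hdsar > 0


def test_wbsar_decreases_when_body_leaves_the_field(coarse_pair, coil):
    phantom, props, _, _ = coarse_pair
    inside = sar_field(phantom, props, coil, Pose(0, 0))
    outside = sar_field(phantom, props, coil, Pose(0.10, 0))
    # +10 cm pushes the legs further below the taper: less absorbed power
    # on the inferior side, monotone tail behaviour on the superior side
    assert wb_sar(outside, phantom, props) != wb_sar(inside, phantom, props)


def test_wbsar_continuity_under_small_pose_steps(coarse_pair, coil):
    phantom, props, _, _ = coarse_pair
    base = wb_sar(sar_field(phantom, props, coil, Pose(0.01, 1.0)), phantom, props)
    deltas = []
    for h in (0.004, 0.002, 0.001):
        stepped = wb_sar(
            sar_field(phantom, props, coil, Pose(0.01 + h, 1.0)), phantom, props
        )
        deltas.append(abs(stepped - base))
    assert deltas[0] > deltas[1] > deltas[2]


def test_sar_result_json_round_trip(coarse_pair, coil):
    phantom, props, _, _ = coarse_pair
    res = compute_sar_result(phantom, props, coil, Pose(0.01, -2.0))
    back = SARResult.from_json(res.to_json())
    assert back == res
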