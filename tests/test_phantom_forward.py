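"""Synthetic phantom and the multislab encoding operator."""

import numpy as np
import pytest

from mslab.bloch import SignalProfile, SlabAcquisition
from mslab.forward import (
    CoilSensitivities,
    MultislabKspace,
    SlabProfileSet,
    calibration_images,
    flat_profiles,
    fold,
    forward_encode,
    forward_encode_adjoint,
    integrate_profiles,
    simulate_multislab_study,
    unfold,
)
from mslab.phantom import PartialVolumeMaps, make_synthetic_phantom, t2w_intensity


@pytest.fixture(scope="module")
def acq9():
    return SlabAcquisition(n_slabs=9, TR=2000.0)


@pytest.fixture(scope="module")
def small_phantom(acq9):
    return make_synthetic_phantom((32, 32, acq9.total_slices), seed=11)


def _profile(acq, s, values):
    return SignalProfile(values=values, tissue="WM", slab_index=s,
                         center_slice=acq.slab_center_slice(s))


def test_phantom_is_deterministic(acq9, small_phantom):
    vol, pv = small_phantom
    vol2, pv2 = make_synthetic_phantom((32, 32, acq9.total_slices), seed=11)
    np.testing.assert_array_equal(vol.data, vol2.data)
    np.testing.assert_array_equal(pv.wm, pv2.wm)
    vol3, _ = make_synthetic_phantom((32, 32, acq9.total_slices), seed=12)
    assert not np.array_equal(vol.data, vol3.data)


def test_partial_volume_invariants(small_phantom):
    _, pv = small_phantom
    for arr in (pv.wm, pv.gm, pv.csf):
        assert arr.min() >= 0.0 and arr.max() <= 1.0
    assert pv.total().max() <= 1.0 + 1e-9
    # all three tissues are actually present in bulk
    for t in ("WM", "GM", "CSF"):
        assert pv.tissue_mask(t, 0.8).sum() > 50


def test_pure_tissue_intensity_ordering():
    """At TE = 78 ms the T2 values order pure-voxel signal CSF > GM > WM."""
    ones = np.ones((1, 1, 1))
    zeros = np.zeros((1, 1, 1))
    wm = t2w_intensity(PartialVolumeMaps(ones, zeros, zeros))
    gm = t2w_intensity(PartialVolumeMaps(zeros, ones, zeros))
    csf = t2w_intensity(PartialVolumeMaps(zeros, zeros, ones))
    assert csf > gm > wm


def test_phantom_shape_validation(acq9):
    with pytest.raises(ValueError):
        make_synthetic_phantom((16, 16, acq9.total_slices))
    with pytest.raises(ValueError):
        make_synthetic_phantom((32, 32, 4))


def test_integrate_profiles_identities(acq9):
    nz = acq9.total_slices
    rng = np.random.default_rng(0)
    prof_a = [_profile(acq9, s, rng.uniform(0.2, 1.0, nz)) for s in range(9)]
    prof_b = [_profile(acq9, s, rng.uniform(0.2, 1.0, nz)) for s in range(9)]
    wm = np.zeros((4, 4, nz))
    csf = np.zeros((4, 4, nz))
    wm[0, 0] = 1.0  # pure WM voxel column
    wm[1, 1] = 0.5  # 50/50 voxel column
    csf[1, 1] = 0.5
    pv = PartialVolumeMaps(wm=wm, gm=np.zeros_like(wm), csf=csf)
    S = integrate_profiles(pv, {"WM": prof_a, "CSF": prof_b}, acq9)
    np.testing.assert_allclose(S.values[3, 0, 0], prof_a[3].values)  # pure tissue
    np.testing.assert_allclose(  # 50/50 -> arithmetic mean
        S.values[3, 1, 1], 0.5 * (prof_a[3].values + prof_b[3].values)
    )
    np.testing.assert_allclose(S.values[:, 2, 2], 0.0)  # background
    # identical profiles for all tissues -> any composition returns them
    S2 = integrate_profiles(pv, {"WM": prof_a, "CSF": prof_a}, acq9)
    np.testing.assert_allclose(S2.values[5, 1, 1], prof_a[5].values)


def test_integrate_profiles_grid_mismatch(acq9):
    pv = PartialVolumeMaps(*(np.zeros((4, 4, 10)),) * 3)
    prof = [_profile(acq9, s, np.ones(acq9.total_slices)) for s in range(9)]
    with pytest.raises(ValueError):
        integrate_profiles(pv, {"WM": prof}, acq9)


def test_adjoint_identity(acq9):
    """<E u, d> == <u, E^H d> to 1e-10 on random complex inputs."""
    nz = acq9.total_slices
    rng = np.random.default_rng(5)
    S = SlabProfileSet(
        values=rng.standard_normal((9, 12, 12, nz)) + 1j * rng.standard_normal((9, 12, 12, nz)),
        acq=acq9,
    )
    C = CoilSensitivities.synthetic((12, 12, nz), 3, seed=2)
    u = rng.standard_normal((12, 12, nz)) + 1j * rng.standard_normal((12, 12, nz))
    d = forward_encode(u, S, C)
    dr = rng.standard_normal(d.data.shape) + 1j * rng.standard_normal(d.data.shape)
    lhs = np.vdot(dr, d.data)
    rhs = np.vdot(forward_encode_adjoint(MultislabKspace(dr, acq9), S, C), u)
    assert abs(lhs - rhs) / (np.linalg.norm(u) * np.linalg.norm(dr)) < 1e-10


def test_linearity(acq9):
    nz = acq9.total_slices
    rng = np.random.default_rng(6)
    S = SlabProfileSet(values=rng.uniform(0.1, 1.0, (9, 1, 1, nz)), acq=acq9)
    u1 = rng.standard_normal((8, 8, nz)) + 1j * rng.standard_normal((8, 8, nz))
    u2 = rng.standard_normal((8, 8, nz))
    a, b = 1.7 - 0.3j, -2.2 + 0.9j
    lhs = forward_encode(a * u1 + b * u2, S).data
    rhs = a * forward_encode(u1, S).data + b * forward_encode(u2, S).data
    np.testing.assert_allclose(lhs, rhs, atol=1e-12 * np.abs(lhs).max())


def test_single_full_fov_slab_is_plain_fft_and_parseval():
    acq1 = SlabAcquisition(n_slabs=1, slices_per_slab=24, overlap_slices=0)
    S = flat_profiles(acq1, support_only=False)
    rng = np.random.default_rng(7)
    u = rng.standard_normal((8, 8, 24)) + 1j * rng.standard_normal((8, 8, 24))
    d = forward_encode(u, S)
    np.testing.assert_allclose(d.data[0, 0], np.fft.fftn(u, norm="ortho"), atol=1e-12)
    assert np.linalg.norm(d.data) == pytest.approx(np.linalg.norm(u), rel=1e-10)


def test_fold_matches_brute_force_and_unfold_is_adjoint():
    rng = np.random.default_rng(8)
    w = rng.standard_normal((3, 3, 74))
    z0, period = 14, 10
    brute = np.zeros((3, 3, period))
    for z in range(74):
        brute[..., (z - z0) % period] += w[..., z]
    np.testing.assert_allclose(fold(w, z0, period), brute, atol=1e-13)
    f = rng.standard_normal((3, 3, period))
    lhs = np.vdot(f, fold(w, z0, period))
    rhs = np.vdot(unfold(f, z0, period, 74), w)
    assert lhs == pytest.approx(rhs, rel=1e-12)


def test_side_lobe_aliasing_matches_fold_oracle(acq9):
    """A profile with a side lobe one slab separation away folds that
    signal into the slab image exactly as direct periodic summation."""
    nz = acq9.total_slices
    s = 4
    vals = np.zeros((9, 1, 1, nz))
    i0 = acq9.slab_start(s)
    vals[s, 0, 0, i0 : i0 + 10] = 1.0
    lobe = i0 + 10 + 2  # inside the next slab's territory
    vals[s, 0, 0, lobe] = 0.3
    S = SlabProfileSet(values=vals, acq=acq9)
    rng = np.random.default_rng(9)
    u = rng.uniform(0.5, 1.0, (6, 6, nz))
    d = forward_encode(u, S)
    img = np.fft.ifftn(d.data[s, 0], norm="ortho")
    w = u * vals[s]
    expect = fold(w.astype(complex), i0, 10)
    np.testing.assert_allclose(img, expect, atol=1e-10)
    # the lobe lands folded onto slab-relative slice (lobe - i0) mod 10
    assert np.abs(img[..., (lobe - i0) % 10] - (u[..., lobe] * 0.3 + w[..., i0 + 2])).max() < 1e-10


def test_calibration_images_alias_free(acq9, small_phantom):
    """2x-FOV calibration shows the side lobes unfolded: it matches the
    profile-weighted truth on the doubled window, and the energy outside
    that window is negligible."""
    vol, pv = small_phantom
    nz = acq9.total_slices
    rng = np.random.default_rng(10)
    # smooth profiles with side lobes confined near each slab
    vals = np.zeros((9, 1, 1, nz))
    z = np.arange(nz)
    for s in range(9):
        c = acq9.slab_start(s) + 4.5
        vals[s, 0, 0] = np.exp(-((z - c) ** 2) / (2 * 2.5**2))
    S = SlabProfileSet(values=vals, acq=acq9)
    d, calib = simulate_multislab_study(vol, S, oversample_calibration=True)
    s = 4
    z0 = acq9.slab_start(s) - 5
    win = np.zeros(nz, bool)
    win[max(z0, 0) : z0 + 20] = True
    direct = vol.data * vals[s]
    rel = np.abs(calib[s][..., win] - direct[..., win]).max() / np.abs(direct).max()
    assert rel < 1e-3
    outside = (np.abs(direct[..., ~win]) ** 2).sum() / (np.abs(direct) ** 2).sum()
    assert outside < 1e-3


def test_flat_profiles_stitch_exactly(acq9, small_phantom):
    """With unit support-only profiles the slab images tile the phantom."""
    from mslab.recon import slab_images

    vol, _ = small_phantom
    S = flat_profiles(acq9, support_only=True)
    d, _ = simulate_multislab_study(vol, S, oversample_calibration=False)
    imgs = slab_images(d)
    # average covering slabs at every slice reproduces the phantom
    support = np.zeros((9, acq9.total_slices))
    for s in range(9):
        support[s, acq9.slab_start(s) : acq9.slab_start(s) + 10] = 1.0
    num = np.abs(imgs).sum(axis=0)
    den = support.sum(axis=0)
    np.testing.assert_allclose(num / den, vol.data, atol=1e-10 * vol.data.max())


def test_kspace_geometry_validation(acq9):
    with pytest.raises(ValueError):
        MultislabKspace(data=np.zeros((9, 1, 4, 4, 7), dtype=complex), acq=acq9)
    with pytest.raises(ValueError):
        calibration_images(
            MultislabKspace(data=np.zeros((9, 1, 4, 4, 10), dtype=complex), acq=acq9)
        )
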