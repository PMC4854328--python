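"""Unit tests for WA, profile estimation, PEN, NPEN building blocks."""

import numpy as np
import pytest

from mslab.bloch import SlabAcquisition
from mslab.evaluate import evaluate_rmse, scan_time_efficiency
from mslab.forward import (
    CoilSensitivities,
    MultislabKspace,
    SlabProfileSet,
    flat_profiles,
    forward_encode,
    simulate_multislab_study,
)
from mslab.phantom import PartialVolumeMaps, make_synthetic_phantom
from mslab.recon import (
    ReconConfig,
    build_frequency_penalty,
    estimate_profiles_sos,
    fermi_window,
    initial_profile_guess,
    recon_npen,
    recon_pen,
    recon_wa,
    tune_initial_regularization,
)


@pytest.fixture(scope="module")
def toy_acq():
    """2 slabs x 5 slices with 2-slice overlap -> 8 reconstructed slices."""
    return SlabAcquisition(n_slabs=2, slices_per_slab=5, overlap_slices=2, TR=2000.0)


@pytest.fixture(scope="module")
def toy_problem(toy_acq):
    rng = np.random.default_rng(21)
    nz = toy_acq.total_slices
    vals = rng.uniform(0.3, 1.0, (2, 4, 4, nz))
    S = SlabProfileSet(values=vals, acq=toy_acq)
    u = rng.standard_normal((4, 4, nz)) + 1j * rng.standard_normal((4, 4, nz))
    d = forward_encode(u, S)
    return u, S, d


def test_fermi_window_values():
    """Center weight ~1; the outermost slice is suppressed below 0.5 with
    the default radius n/2 - overlap and unit width."""
    w = fermi_window(10, overlap=2)
    assert w[4] > 0.9  # ~1 at the slab center (two middle samples)
    assert w[4] == pytest.approx(w[5], rel=1e-12)
    assert w[0] < 0.5 and w[-1] < 0.5
    assert np.all(w > 0)
    np.testing.assert_allclose(w, w[::-1], rtol=1e-12)  # symmetric


def test_wa_degenerate_window_stitches_truth(toy_acq):
    """Flat support-only profiles + near-rectangular Fermi: exact stitch."""
    rng = np.random.default_rng(22)
    nz = toy_acq.total_slices
    u = rng.uniform(0.5, 1.0, (6, 6, nz))
    S = flat_profiles(toy_acq, support_only=True)
    d, _ = simulate_multislab_study(u, S, oversample_calibration=False)
    out = recon_wa(d, fermi_radius=2.49, fermi_width=1e-3)
    np.testing.assert_allclose(np.abs(out), u, atol=1e-8)


def test_sos_profiles_two_flat_overlapping_slabs(toy_acq):
    """Two unit slab images: profile is 1/sqrt(2) in the overlap, 1 elsewhere."""
    nz = toy_acq.total_slices
    calib = np.zeros((2, 4, 4, nz), dtype=complex)
    calib[0, ..., 0:5] = 1.0
    calib[1, ..., 3:8] = 1.0
    S = estimate_profiles_sos(calib, toy_acq, hamming=False)
    v = S.values[0, 0, 0].real
    np.testing.assert_allclose(v[0:3], 1.0, atol=1e-12)
    np.testing.assert_allclose(v[3:5], 1 / np.sqrt(2), atol=1e-12)
    np.testing.assert_allclose(v[5:], 0.0, atol=1e-12)


def test_sos_profiles_constant_unchanged_by_hamming(toy_acq):
    nz = toy_acq.total_slices
    calib = np.ones((2, 8, 8, nz), dtype=complex)
    s_plain = estimate_profiles_sos(calib, toy_acq, hamming=False)
    s_ham = estimate_profiles_sos(calib, toy_acq, hamming=True)
    np.testing.assert_allclose(s_ham.values, s_plain.values, atol=1e-10)


def test_sos_profiles_all_zero_rejected(toy_acq):
    with pytest.raises(ValueError):
        estimate_profiles_sos(np.zeros((2, 4, 4, toy_acq.total_slices)), toy_acq)


def test_initial_profile_guess_arithmetic(toy_acq):
    """Toy image with a hand-picked mask: slice averages equal hand-computed
    masked means, normalized at the slab center slice."""
    nz = toy_acq.total_slices
    calib = np.zeros((2, 2, 2, nz))
    mask = np.zeros((2, 2, nz), bool)
    mask[0, 0, :] = True
    mask[1, 1, :] = True
    for z in range(nz):
        calib[0, 0, 0, z] = z + 1.0
        calib[0, 1, 1, z] = 3 * (z + 1.0)
        calib[1, 0, 0, z] = 5.0
        calib[1, 1, 1, z] = 7.0
    S = initial_profile_guess(calib, toy_acq, mask)
    iave = np.array([2 * (z + 1.0) for z in range(nz)])  # mean of the two masked voxels
    zc = toy_acq.slab_center_slice(0)
    np.testing.assert_allclose(S.values[0, 0, 0], iave / iave[zc], rtol=1e-12)
    # scale invariance
    S2 = initial_profile_guess(calib * 7.3, toy_acq, mask)
    np.testing.assert_allclose(S2.values, S.values, rtol=1e-12)


def test_initial_profile_guess_inverts_separable_image(toy_acq):
    """image = profile(z) * constant inside the mask -> recovered exactly."""
    nz = toy_acq.total_slices
    rng = np.random.default_rng(23)
    prof = rng.uniform(0.4, 1.0, nz)
    calib = np.zeros((2, 3, 3, nz))
    calib[0] = 2.5 * prof[None, None, :]
    calib[1] = 1.5 * prof[None, None, :]
    mask = np.ones((3, 3, nz), bool)
    S = initial_profile_guess(calib, toy_acq, mask)
    zc0 = toy_acq.slab_center_slice(0)
    np.testing.assert_allclose(S.values[0, 0, 0], prof / prof[zc0], rtol=1e-12)


def test_initial_profile_guess_empty_mask_hole(toy_acq):
    nz = toy_acq.total_slices
    calib = np.ones((2, 2, 2, nz))
    mask = np.ones((2, 2, nz), bool)
    mask[:, :, 2] = False  # hole inside coverage
    with pytest.raises(ValueError):
        initial_profile_guess(calib, toy_acq, mask)


def test_frequency_penalty_geometry():
    """(9,10,2) at 1.5 mm -> slab separation 12 mm, first bump at 1/12 mm^-1,
    zero DC weight; n_harmonics=0 disables the penalty."""
    acq = SlabAcquisition(n_slabs=9)
    pen = build_frequency_penalty(acq, sigma_k=0.2)
    assert pen.d_slab_mm == pytest.approx(12.0)
    kz = np.fft.fftfreq(acq.total_slices, d=1.5)
    near_fund = np.argmin(np.abs(kz - 1.0 / 12.0))
    assert pen.weights[near_fund] > 0.9 * pen.weights.max()
    assert pen.weights[0] < 1e-3 * pen.weights.max()
    assert build_frequency_penalty(acq, n_harmonics=0).weights.max() == 0.0
    with pytest.raises(ValueError):
        build_frequency_penalty(acq, sigma_k=1.0)


def test_frequency_penalty_spectral_selectivity():
    acq = SlabAcquisition(n_slabs=9)
    pen = build_frequency_penalty(acq)
    nz = acq.total_slices
    z = np.arange(nz) * acq.slice_thickness
    sine = np.sin(2 * np.pi * z / 12.0)[None, None, :]
    const = np.ones((1, 1, nz))

    def pnorm(u):
        return np.linalg.norm(pen.weights * np.fft.fft(u, axis=-1, norm="ortho"))

    assert pnorm(sine) > 1.0
    # DC leakage is bounded by the 1e-3 design floor on the Gaussian bumps
    assert pnorm(const) < 1e-3 * pnorm(sine)


def test_regularization_schedule_exact():
    cfg = ReconConfig(alpha0=0.2, beta0=0.4, decay=1.5, beta_floor=0.03)
    for n in range(12):
        assert cfg.alpha(n) == 0.2 / 1.5**n
        assert cfg.beta(n) == max(0.4 / 1.5**n, 0.03)
    with pytest.raises(ValueError):
        ReconConfig(decay=0.9)


def test_pen_exact_profiles_recover_phantom(toy_problem):
    u, S, d = toy_problem
    cfg = ReconConfig(cg_iters=600, cg_tol=1e-12, pen_epsilon_rel=0.0)
    u_hat, info = recon_pen(d, S, config=cfg)
    assert np.linalg.norm(u_hat - u) / np.linalg.norm(u) < 1e-6
    assert info["converged"]


def test_pen_matches_dense_pseudo_inverse(toy_acq, toy_problem):
    """CG solution equals the explicit pseudo-inverse on the 8-z-voxel toy."""
    u, S, d = toy_problem
    nx, ny, nz = u.shape
    n = nx * ny * nz
    cols = []
    for i in range(n):
        e = np.zeros(n, dtype=complex)
        e[i] = 1.0
        cols.append(forward_encode(e.reshape(u.shape), S).data.ravel())
    A = np.array(cols).T
    u_pinv = (np.linalg.pinv(A) @ d.data.ravel()).reshape(u.shape)
    cfg = ReconConfig(cg_iters=300, cg_tol=1e-12, pen_epsilon_rel=0.0)
    u_cg, _ = recon_pen(d, S, config=cfg)
    assert np.linalg.norm(u_cg - u_pinv) / np.linalg.norm(u_pinv) < 1e-8


def test_npen_linear_subcase_with_true_initialization(toy_acq):
    """Flat unit profiles and S0 = truth: the first Gauss-Newton step
    already fits the data and recovers the phantom."""
    rng = np.random.default_rng(24)
    nz = toy_acq.total_slices
    u = rng.uniform(0.5, 1.5, (4, 4, nz))
    # rectangular unit slabs: without support restriction the kz fold is
    # genuinely unresolvable (identical profiles carry no encoding power)
    S = flat_profiles(toy_acq, shape_xy=(1, 1), support_only=True)
    d = forward_encode(u, S)
    cfg = ReconConfig(alpha0=1e-6, beta0=0.0, max_outer_iters=1, burn_in=0,
                      cg_iters=600, cg_tol=1e-12, update_profiles=False,
                      n_harmonics=0)
    res = recon_npen(d, S0=S, config=cfg)
    assert res.residuals[0] < 1e-3
    assert np.linalg.norm(np.abs(res.u) - u) / np.linalg.norm(u) < 1e-3


def test_npen_with_frozen_true_profiles_equals_pen(toy_problem):
    """beta = 0, profiles frozen at truth, alpha -> 0: the Gauss-Newton
    subproblem is PEN's least-squares problem."""
    u, S, d = toy_problem
    cfg_pen = ReconConfig(cg_iters=600, cg_tol=1e-12, pen_epsilon_rel=0.0)
    u_pen, _ = recon_pen(d, S, config=cfg_pen)
    cfg = ReconConfig(alpha0=1e-10, beta0=0.0, max_outer_iters=1, burn_in=0,
                      cg_iters=600, cg_tol=1e-12, update_profiles=False,
                      n_harmonics=0)
    res = recon_npen(d, S0=S, config=cfg)
    # the toy operator has kappa ~ 3e6; CG residual 1e-12 bounds the
    # solution difference near kappa * tol relative
    assert np.linalg.norm(res.u - u_pen) / np.linalg.norm(u_pen) < 1e-4


def test_npen_diagnostics_shapes_and_cg_bound(toy_problem):
    u, S, d = toy_problem
    cfg = ReconConfig(max_outer_iters=5, burn_in=2, cg_iters=400, cg_tol=1e-8)
    res = recon_npen(d, S0=S, config=cfg)
    assert len(res.du_norms) == len(res.residuals) == 5
    assert len(res.alphas) == len(res.betas) == 5
    for info in res.cg_info:
        assert info["rel_residual"] < cfg.cg_tol
    assert 3 <= res.stop_iteration <= 5  # burn-in respected


def test_tune_initial_regularization(toy_problem):
    u, S, d = toy_problem
    grid = [(0.05, 0.1), (0.2, 0.4), (1.0, 2.0), (5.0, 10.0)]
    base = ReconConfig(cg_iters=100, cg_tol=1e-8)
    a0, b0 = tune_initial_regularization(d, S, grid, config=base)
    cfg = ReconConfig(**{**base.__dict__, "alpha0": a0, "beta0": b0,
                         "max_outer_iters": 1, "burn_in": 0})
    res = recon_npen(d, S0=S, config=cfg, keep_iterates=False)
    ratios = []
    for aa, bb in grid:
        c = ReconConfig(**{**base.__dict__, "alpha0": aa, "beta0": bb,
                           "max_outer_iters": 1, "burn_in": 0})
        r = recon_npen(d, S0=S, config=c, keep_iterates=False)
        ratios.append(r.residuals[0])
    assert abs(res.residuals[0] - 0.75) == pytest.approx(min(abs(np.array(ratios) - 0.75)),
                                                         abs=1e-12)
    # residual ratio after one step is non-decreasing in alpha0 at fixed beta0
    rs = []
    for aa in (0.01, 0.1, 1.0, 10.0):
        c = ReconConfig(**{**base.__dict__, "alpha0": aa, "beta0": 0.2,
                           "max_outer_iters": 1, "burn_in": 0})
        rs.append(recon_npen(d, S0=S, config=c, keep_iterates=False).residuals[0])
    assert np.all(np.diff(rs) >= -1e-9)
    with pytest.raises(ValueError):
        tune_initial_regularization(d, S, [])


def test_evaluate_rmse_closed_forms():
    rng = np.random.default_rng(25)
    nz = 12
    pvv = np.zeros((6, 6, nz))
    pvv[1:5, 1:5, :] = 1.0
    pv = PartialVolumeMaps(wm=pvv * 0.9, gm=np.zeros_like(pvv), csf=np.zeros_like(pvv))
    truth = rng.uniform(0.5, 1.5, (6, 6, nz))
    truth /= truth[pv.brain_mask()].mean()  # unit-normalized
    rep = evaluate_rmse(truth, truth, pv)
    assert rep.rmse == 0.0 and rep.rmse_tissue["WM"] == 0.0
    assert np.isnan(rep.rmse_tissue["CSF"])  # empty mask -> undefined, not 0
    c = 0.2
    rep2 = evaluate_rmse(truth + c, truth, pv, match_scale=False)
    assert rep2.rmse == pytest.approx(c, rel=1e-9)


def test_evaluate_threshold_is_strict():
    nz = 8
    wm = np.full((4, 4, nz), 0.8)  # exactly at threshold -> excluded
    wm[0, 0, :] = 0.81
    pv = PartialVolumeMaps(wm=wm, gm=np.zeros_like(wm), csf=np.zeros_like(wm))
    assert pv.tissue_mask("WM", 0.8).sum() == nz


def test_scan_time_efficiency():
    assert scan_time_efficiency(0.4) == pytest.approx(100.0 / 1.4)
    with pytest.raises(ValueError):
        scan_time_efficiency(-0.1)
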