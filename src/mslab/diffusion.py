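"""Partial-volume diffusion bias at slab boundaries.

A voxel containing two tissue compartments produces the diffusion signal

    M(b, v) = sum_i M0_i f_i exp(-b v^T D_i v),        sum_i f_i = 1,

where ``f_i`` are volume fractions, ``D_i`` diffusion tensors and ``M0_i``
the b=0 amplitudes of each compartment, taken from the Bloch-simulated
steady-state slab profiles.  Because slab crosstalk attenuates each tissue's
M0 differently (T1-dependent), the *effective* compartment mixture differs
between slab center and slab boundary, so fitted FA and MD acquire a bias
that normalization by the b=0 image cannot remove.  This module quantifies
that bias over a (WM fraction) x (b value) grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bloch import (
    CSF,
    GM,
    WM,
    SignalProfile,
    SlabAcquisition,
    simulate_profile,
)
from .pulses import design_slr_pulse

__all__ = [
    "TISSUE_EIGENVALUES",
    "DiffusionCompartment",
    "DiffusionProtocol",
    "jones6_directions",
    "tensor_from_eigenvalues",
    "pv_signal",
    "fit_dti",
    "fa_from_eigenvalues",
    "BiasSurface",
    "bias_surface",
    "default_bias_grid",
    "center_boundary_m0",
    "combined_center_boundary_m0",
    "reference_m0",
]

# Diffusion tensor eigenvalues in 1e-3 mm^2/s: WM prolate (FA = 0.707),
# GM and CSF isotropic.
TISSUE_EIGENVALUES = {
    "WM": (1.4, 0.35, 0.35),
    "GM": (0.7, 0.7, 0.7),
    "CSF": (3.0, 3.0, 3.0),
}


def jones6_directions() -> np.ndarray:
    """Six noncollinear unit gradient directions (dual-gradient scheme)."""
    v = np.array(
        [
            [1, 1, 0],
            [1, -1, 0],
            [1, 0, 1],
            [1, 0, -1],
            [0, 1, 1],
            [0, 1, -1],
        ],
        dtype=float,
    )
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def tensor_from_eigenvalues(eigenvalues, principal_axis: int = 0) -> np.ndarray:
    """Diagonal tensor with the largest eigenvalue on ``principal_axis``."""
    lam = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    order = [principal_axis] + [i for i in range(3) if i != principal_axis]
    d = np.zeros((3, 3))
    for lam_i, ax in zip(lam, order):
        d[ax, ax] = lam_i
    return d


@dataclass(frozen=True)
class DiffusionCompartment:
    """One tissue compartment of the partial-volume signal model."""

    name: str
    fraction: float
    tensor: np.ndarray  # 3x3, units 1e-3 mm^2/s
    m0_center: float = 1.0
    m0_boundary: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")
        t = np.asarray(self.tensor, dtype=float)
        if t.shape != (3, 3) or not np.allclose(t, t.T):
            raise ValueError("tensor must be symmetric 3x3")
        if np.linalg.eigvalsh(t).min() < -1e-12:
            raise ValueError("tensor eigenvalues must be >= 0")
        object.__setattr__(self, "tensor", t)


@dataclass(frozen=True)
class DiffusionProtocol:
    """Diffusion weighting: single shell b (s/mm^2) + unit directions."""

    b: float
    directions: np.ndarray
    include_b0: bool = True

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError("b must be >= 0")
        v = np.atleast_2d(np.asarray(self.directions, dtype=float))
        if not np.allclose(np.linalg.norm(v, axis=1), 1.0, atol=1e-8):
            raise ValueError("directions must be unit vectors")
        object.__setattr__(self, "directions", v)


def pv_signal(
    compartments: list[DiffusionCompartment],
    protocol: DiffusionProtocol,
    location: str = "center",
) -> np.ndarray:
    """Partial-volume diffusion signal per direction (b0 first if requested).

    ``M(b,v) = sum_i M0_i(location) f_i exp(-b v^T D_i v)`` with b in s/mm^2
    and tensors in 1e-3 mm^2/s.
    """
    if location not in ("center", "boundary"):
        raise ValueError("location must be 'center' or 'boundary'")
    fsum = sum(c.fraction for c in compartments)
    if abs(fsum - 1.0) > 1e-8:
        raise ValueError(f"compartment fractions must sum to 1 (got {fsum})")
    v = protocol.directions
    out = np.zeros(v.shape[0])
    s0 = 0.0
    for c in compartments:
        m0 = c.m0_center if location == "center" else c.m0_boundary
        adc = np.einsum("ij,jk,ik->i", v, c.tensor, v)  # 1e-3 mm^2/s
        out += m0 * c.fraction * np.exp(-protocol.b * 1e-3 * adc)
        s0 += m0 * c.fraction
    if protocol.include_b0:
        out = np.concatenate([[s0], out])
    return out


def _design_matrix(protocol: DiffusionProtocol) -> np.ndarray:
    v = protocol.directions
    b = protocol.b * 1e-3  # pair with tensors in 1e-3 mm^2/s
    rows = [
        np.column_stack(
            [
                np.ones(v.shape[0]),
                -b * v[:, 0] ** 2,
                -b * v[:, 1] ** 2,
                -b * v[:, 2] ** 2,
                -2 * b * v[:, 0] * v[:, 1],
                -2 * b * v[:, 0] * v[:, 2],
                -2 * b * v[:, 1] * v[:, 2],
            ]
        )
    ]
    if protocol.include_b0:
        rows.insert(0, np.array([[1.0, 0, 0, 0, 0, 0, 0]]))
    x = np.vstack(rows)
    if np.linalg.matrix_rank(x) < 7:
        raise ValueError("direction set is rank deficient for a tensor fit")
    return x


def fit_dti(signals: np.ndarray, protocol: DiffusionProtocol):
    """Log-linear least-squares diffusion tensor fit.

    Returns ``(tensor, md, fa)`` with the tensor in 1e-3 mm^2/s.  Signals
    must be positive and ordered like the output of :func:`pv_signal`.
    """
    signals = np.asarray(signals, dtype=float)
    if np.any(signals <= 0):
        raise ValueError("signals must be positive for a log-linear fit")
    x = _design_matrix(protocol)
    coef, *_ = np.linalg.lstsq(x, np.log(signals.T), rcond=None)
    dxx, dyy, dzz, dxy, dxz, dyz = coef[1:7]
    tensor = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    lam = np.linalg.eigvalsh(tensor)
    md = float(lam.mean())
    fa = fa_from_eigenvalues(lam)
    return tensor, md, fa


def fa_from_eigenvalues(eigenvalues) -> float:
    """Fractional anisotropy from tensor eigenvalues."""
    lam = np.asarray(eigenvalues, dtype=float)
    lbar = lam.mean()
    denom = np.sum(lam**2)
    if denom == 0:
        return 0.0
    return float(np.sqrt(1.5 * np.sum((lam - lbar) ** 2) / denom))


@dataclass
class BiasSurface:
    """FA / MD bias between slab boundary and slab center over (f_wm, b)."""

    wm_fractions: np.ndarray  # in [0, 1]
    b_values: np.ndarray  # s/mm^2
    fa_error: np.ndarray  # |FA_center - FA_boundary|, shape (n_f, n_b)
    md_relative_error: np.ndarray  # |MD_c - MD_b| / MD_c
    fa_center: np.ndarray

    def max_fa_error(self) -> float:
        return float(self.fa_error.max())

    def max_md_relative_error_percent(self) -> float:
        return float(self.md_relative_error.max() * 100.0)

    def argmax_fa_error(self) -> tuple[float, float]:
        """(WM fraction, b value) at which the FA error peaks."""
        i, j = np.unravel_index(np.argmax(self.fa_error), self.fa_error.shape)
        return float(self.wm_fractions[i]), float(self.b_values[j])


def center_boundary_m0(
    profile: SignalProfile, acq: SlabAcquisition, slab: int | None = None
) -> tuple[float, float, int]:
    """b=0 amplitudes at slab center and boundary from a simulated profile.

    The boundary is the slice with the deepest saturation dip within the
    slab's non-overlapped support; the center is the slab's center slice.
    Returns (m0_center, m0_boundary, boundary_slice).
    """
    if slab is None:
        slab = profile.slab_index
    i0 = acq.slab_start(slab)
    sl = slice(i0, i0 + acq.slices_per_slab)
    vals = profile.values[sl]
    b_rel = int(np.argmin(vals))
    return float(profile.values[profile.center_slice]), float(vals[b_rel]), i0 + b_rel


def default_bias_grid() -> tuple[np.ndarray, np.ndarray]:
    """WM fractions 0..100% in 1% steps; b in {1, 100, 200, ..., 10000}."""
    fr = np.linspace(0.0, 1.0, 101)
    b = np.concatenate([[1.0], np.arange(100.0, 10001.0, 100.0)])
    return fr, b


def bias_surface(
    tissue_pair: tuple[str, str] = ("WM", "CSF"),
    wm_fractions: np.ndarray | None = None,
    b_values: np.ndarray | None = None,
    m0: dict[str, tuple[float, float]] | None = None,
    acq: SlabAcquisition | None = None,
    directions: np.ndarray | None = None,
    principal_axis: int = 0,
) -> BiasSurface:
    """FA / MD bias surfaces for a two-compartment voxel.

    ``m0`` maps tissue name to (center, boundary) b=0 amplitudes; if omitted
    it is computed by Bloch simulation under the reference protocol
    (TR = 2 s, 15-mm slabs, interleaved ordering, the standard pulse pair).
    """
    t1, t2 = tissue_pair
    if t1 != "WM":
        raise ValueError("the first compartment must be WM")
    if t2 not in ("CSF", "GM"):
        raise ValueError("second compartment must be CSF or GM")
    if wm_fractions is None or b_values is None:
        fr_def, b_def = default_bias_grid()
        wm_fractions = fr_def if wm_fractions is None else np.asarray(wm_fractions, float)
        b_values = b_def if b_values is None else np.asarray(b_values, float)
    wm_fractions = np.asarray(wm_fractions, dtype=float)
    b_values = np.asarray(b_values, dtype=float)
    if wm_fractions.size == 0 or b_values.size == 0:
        raise ValueError("fraction and b grids must be nonempty")
    if m0 is None:
        m0 = reference_m0(acq)
    if directions is None:
        directions = jones6_directions()

    d1 = tensor_from_eigenvalues(TISSUE_EIGENVALUES[t1], principal_axis)
    d2 = tensor_from_eigenvalues(TISSUE_EIGENVALUES[t2], principal_axis)
    nf, nb = wm_fractions.size, b_values.size
    fa_err = np.zeros((nf, nb))
    md_err = np.zeros((nf, nb))
    fa_c = np.zeros((nf, nb))
    for j, b in enumerate(b_values):
        proto = DiffusionProtocol(b=float(b), directions=directions)
        x = _design_matrix(proto)
        xp = np.linalg.pinv(x)
        adc1 = np.einsum("ij,jk,ik->i", proto.directions, d1, proto.directions)
        adc2 = np.einsum("ij,jk,ik->i", proto.directions, d2, proto.directions)
        e1 = np.exp(-b * 1e-3 * adc1)
        e2 = np.exp(-b * 1e-3 * adc2)
        for i, f in enumerate(wm_fractions):
            res = {}
            for loc_idx, loc in enumerate(("center", "boundary")):
                a1 = m0[t1][loc_idx] * f
                a2 = m0[t2][loc_idx] * (1.0 - f)
                sig = np.concatenate([[a1 + a2], a1 * e1 + a2 * e2])
                coef = xp @ np.log(sig)
                dxx, dyy, dzz, dxy, dxz, dyz = coef[1:7]
                lam = np.linalg.eigvalsh(
                    np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
                )
                res[loc] = (float(lam.mean()), fa_from_eigenvalues(lam))
            md_c, fa_center = res["center"]
            md_b, fa_boundary = res["boundary"]
            fa_err[i, j] = abs(fa_center - fa_boundary)
            md_err[i, j] = abs(md_c - md_b) / md_c if md_c != 0 else 0.0
            fa_c[i, j] = fa_center
    return BiasSurface(wm_fractions, b_values, fa_err, md_err, fa_c)


def combined_center_boundary_m0(
    profiles: list[SignalProfile], acq: SlabAcquisition, slab: int | None = None
) -> tuple[float, float, int]:
    """Center / boundary b=0 amplitudes of the slab-combination profile.

    In the reconstructed volume every slice in an overlap region carries
    signal from both contributing slabs, so the b=0 amplitude of a boundary
    voxel is the combination (here: plain average over covering slabs) of
    the individual profiles, not a single slab's edge value.  The boundary
    is the minimum of that combined profile between the centers of slab
    ``slab`` and its right neighbor; the center is slab ``slab``'s center
    slice.  Returns (m0_center, m0_boundary, boundary_slice).
    """
    if slab is None:
        slab = acq.n_slabs // 2
    if slab >= acq.n_slabs - 1:
        raise ValueError("need a right neighbor slab to define the boundary")
    stack = np.array([p.values for p in profiles])
    support = np.zeros_like(stack)
    for s in range(acq.n_slabs):
        i0 = acq.slab_start(s)
        support[s, i0 : i0 + acq.slices_per_slab] = 1.0
    combined = (stack * support).sum(axis=0) / support.sum(axis=0)
    lo = acq.slab_center_slice(slab)
    hi = acq.slab_center_slice(slab + 1)
    b_rel = int(np.argmin(combined[lo : hi + 1]))
    return float(combined[lo]), float(combined[lo + b_rel]), lo + b_rel


_REFERENCE_M0_CACHE: dict = {}


def reference_m0(acq: SlabAcquisition | None = None) -> dict[str, tuple[float, float]]:
    """Bloch-simulated (center, boundary) b=0 amplitudes per tissue.

    Reference protocol: TR = 2 s, 15-mm slabs of 10 slices with 2-slice
    overlap, interleaved ordering over 11 slabs, TBW 20/8 pulse pair,
    TE = 78 ms, with the pulse bandwidth mapped onto the 15-mm slab FOV.
    Center and boundary are taken from the slab-combination profile around
    the central slab (see :func:`combined_center_boundary_m0`).
    """
    if acq is None:
        acq = SlabAcquisition(n_slabs=11, TR=2000.0)
    key = (acq.n_slabs, acq.TR, acq.slices_per_slab, acq.overlap_slices,
           acq.slice_thickness, acq.ordering, acq.TE)
    if key in _REFERENCE_M0_CACHE:
        return _REFERENCE_M0_CACHE[key]
    ex = design_slr_pulse(20, 7.18, 256, "excitation", 90.0)
    ref = design_slr_pulse(8, 10.24, 256, "refocusing", 180.0)
    target = acq.n_slabs // 2
    out = {}
    for tissue in (WM, GM, CSF):
        profs = simulate_profile(acq, tissue, ex, ref, target, fov_mode="slab",
                                 _all_slabs=True)
        c, b, _ = combined_center_boundary_m0(profs, acq, target)
        out[tissue.name] = (c, b)
    _REFERENCE_M0_CACHE[key] = out
    return out
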