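"""Linear multislab encoding: d = P F C S u.

Each slab's k-space is the 3D Fourier transform of the image weighted by
that slab's profile S and the coil sensitivity C, sampled on only
``slices_per_slab`` kz lines.  Sampling kz at spacing 1/(slab FOV) is
exactly equivalent to folding the profile-weighted image into the slab FOV
with period ``slices_per_slab`` voxels — the slab-aliasing mechanism: the
profile's side lobes extend beyond the phase-encoded FOV and fold back.

FFTs are unitary (1/sqrt(N)), so the unweighted single-slab operator is
orthonormal and the adjoint is the inverse fold + conjugate weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bloch import SignalProfile, SlabAcquisition
from .phantom import ImageVolume, PartialVolumeMaps

__all__ = [
    "SlabProfileSet",
    "CoilSensitivities",
    "MultislabKspace",
    "integrate_profiles",
    "flat_profiles",
    "forward_encode",
    "forward_encode_adjoint",
    "simulate_multislab_study",
    "fold",
    "unfold",
]


@dataclass
class SlabProfileSet:
    """Per-slab signal weighting on the full-FOV grid.

    ``values`` has shape (n_slabs, nx, ny, nz); in-plane-constant profiles
    may use broadcastable shape (n_slabs, 1, 1, nz).
    """

    values: np.ndarray
    acq: SlabAcquisition

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 4 or self.values.shape[0] != self.acq.n_slabs:
            raise ValueError("profile set must be (n_slabs, nx, ny, nz)")
        if self.values.shape[3] != self.acq.total_slices:
            raise ValueError("profile z extent must match the full FOV")

    @property
    def n_slabs(self) -> int:
        return self.values.shape[0]


@dataclass
class CoilSensitivities:
    """Complex coil maps, shape (n_coils, nx, ny, nz); broadcastable dims ok."""

    maps: np.ndarray

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=complex)
        if self.maps.ndim != 4:
            raise ValueError("coil maps must be (n_coils, nx, ny, nz)")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @staticmethod
    def uniform(shape=(1, 1, 1)) -> "CoilSensitivities":
        return CoilSensitivities(maps=np.ones((1, *shape), dtype=complex))

    @staticmethod
    def synthetic(shape, n_coils: int, seed: int = 0) -> "CoilSensitivities":
        """Smooth synthetic birdcage-like sensitivities around the FOV."""
        nx, ny, nz = shape
        rng = np.random.default_rng(seed)
        x, y = np.meshgrid(np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), indexing="ij")
        maps = np.empty((n_coils, nx, ny, nz), dtype=complex)
        for c in range(n_coils):
            ang = 2 * np.pi * c / n_coils + rng.uniform(-0.2, 0.2)
            cx, cy = 1.3 * np.cos(ang), 1.3 * np.sin(ang)
            r2 = (x - cx) ** 2 + (y - cy) ** 2
            m = np.exp(-r2 / 2.0) * np.exp(1j * 0.5 * (x * np.sin(ang) - y * np.cos(ang)))
            maps[c] = m[:, :, None]
        return CoilSensitivities(maps=maps)


@dataclass
class MultislabKspace:
    """Sampled multislab k-space, shape (n_slabs, n_coils, nx, ny, n_kz)."""

    data: np.ndarray
    acq: SlabAcquisition
    oversampled: bool = False
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 5 or self.data.shape[0] != self.acq.n_slabs:
            raise ValueError("k-space must be (n_slabs, n_coils, nx, ny, n_kz)")
        expected = self.acq.slices_per_slab * (2 if self.oversampled else 1)
        if self.data.shape[4] != expected:
            raise ValueError(
                f"kz line count {self.data.shape[4]} inconsistent with geometry ({expected})"
            )


def _kz_window(acq: SlabAcquisition, slab: int, oversampled: bool) -> tuple[int, int]:
    """(z offset of first folded voxel, fold period) for one slab."""
    n = acq.slices_per_slab
    if oversampled:
        return acq.slab_start(slab) - n // 2, 2 * n
    return acq.slab_start(slab), n


def fold(w: np.ndarray, z0: int, period: int) -> np.ndarray:
    """Fold the last axis with the given period, aligned so that full-grid
    index ``z0`` maps to folded index 0."""
    nz = w.shape[-1]
    out = np.zeros(w.shape[:-1] + (period,), dtype=w.dtype)
    for j in range(period):
        r = (z0 + j) % period
        out[..., j] = w[..., r::period].sum(axis=-1)
    return out


def unfold(f: np.ndarray, z0: int, period: int, nz: int) -> np.ndarray:
    """Adjoint of :func:`fold`: broadcast folded values back to the full grid."""
    idx = (np.arange(nz) - z0) % period
    return f[..., idx]


def forward_encode(
    u: np.ndarray | ImageVolume,
    profiles: SlabProfileSet,
    coils: CoilSensitivities | None = None,
    oversampled: bool = False,
) -> MultislabKspace:
    """Apply the multislab encoding operator E to an image."""
    if isinstance(u, ImageVolume):
        u = u.data
    u = np.asarray(u)
    acq = profiles.acq
    nz = acq.total_slices
    if u.ndim != 3 or u.shape[2] != nz:
        raise ValueError("image grid inconsistent with slab geometry")
    if coils is None:
        coils = CoilSensitivities.uniform()
    n = acq.slices_per_slab * (2 if oversampled else 1)
    nx, ny = u.shape[:2]
    out = np.empty((acq.n_slabs, coils.n_coils, nx, ny, n), dtype=complex)
    for s in range(acq.n_slabs):
        ws = u * profiles.values[s]
        z0, period = _kz_window(acq, s, oversampled)
        for c in range(coils.n_coils):
            w = ws * np.broadcast_to(coils.maps[c], u.shape)
            out[s, c] = np.fft.fftn(fold(w, z0, period), norm="ortho")
    return MultislabKspace(data=out, acq=acq, oversampled=oversampled)


def forward_encode_adjoint(
    d: MultislabKspace,
    profiles: SlabProfileSet,
    coils: CoilSensitivities | None = None,
) -> np.ndarray:
    """Adjoint operator E^H applied to k-space data."""
    acq = d.acq
    nz = acq.total_slices
    if coils is None:
        coils = CoilSensitivities.uniform()
    nx, ny = d.data.shape[2:4]
    out = np.zeros((nx, ny, nz), dtype=complex)
    for s in range(acq.n_slabs):
        z0, period = _kz_window(acq, s, d.oversampled)
        for c in range(coils.n_coils):
            img = unfold(np.fft.ifftn(d.data[s, c], norm="ortho"), z0, period, nz)
            out += img * np.conj(profiles.values[s] * np.broadcast_to(coils.maps[c], out.shape))
    return out


def integrate_profiles(
    pv: PartialVolumeMaps,
    tissue_profiles: dict[str, list[SignalProfile]],
    acq: SlabAcquisition,
) -> SlabProfileSet:
    """PV-weighted combination of tissue-specific slab profiles.

    Per voxel: ``S_s = sum_t pv_t * profile_t,s(z) / sum_t pv_t``; voxels
    with zero total tissue fraction get zero weight.
    """
    nz = acq.total_slices
    if pv.wm.shape[2] != nz:
        raise ValueError("partial volume maps do not match the slab geometry grid")
    for name, profs in tissue_profiles.items():
        if len(profs) != acq.n_slabs:
            raise ValueError(f"need one {name} profile per slab")
        for p in profs:
            if p.values.size != nz:
                raise ValueError("tissue profiles must be on the full-FOV slice grid")
    total = pv.total()
    denom = np.where(total > 1e-9, total, 1.0)
    values = np.zeros((acq.n_slabs, *pv.wm.shape))
    pv_maps = pv.as_dict()
    for s in range(acq.n_slabs):
        acc = np.zeros_like(pv.wm)
        for name, profs in tissue_profiles.items():
            acc += pv_maps[name.upper()] * profs[s].values[None, None, :]
        values[s] = acc / denom * (total > 1e-9)
    return SlabProfileSet(values=values, acq=acq)


def flat_profiles(acq: SlabAcquisition, shape_xy=(1, 1), support_only: bool = True) -> SlabProfileSet:
    """Unit profiles, either restricted to each slab's support or full-FOV flat."""
    nz = acq.total_slices
    values = np.zeros((acq.n_slabs, *shape_xy, nz))
    for s in range(acq.n_slabs):
        if support_only:
            i0 = acq.slab_start(s)
            values[s, ..., i0 : i0 + acq.slices_per_slab] = 1.0
        else:
            values[s] = 1.0
    return SlabProfileSet(values=values, acq=acq)


def simulate_multislab_study(
    phantom: ImageVolume | np.ndarray,
    profiles: SlabProfileSet,
    coils: CoilSensitivities | None = None,
    oversample_calibration: bool = True,
    noise_std: float = 0.0,
    seed: int = 0,
):
    """Encode a phantom into undersampled multislab k-space (+ calibration).

    Returns ``(kspace, calibration)`` where ``calibration`` is an array of
    zero-padded aliasing-free slab images, shape (n_slabs, nx, ny, nz)
    (None when ``oversample_calibration`` is False).  Optional complex
    Gaussian noise is seeded and added to the sampled k-space.
    """
    if isinstance(phantom, ImageVolume):
        u = phantom.data
    else:
        u = np.asarray(phantom)
    acq = profiles.acq
    d = forward_encode(u, profiles, coils)
    rng = np.random.default_rng(seed)
    if noise_std > 0:
        d.data += noise_std * (
            rng.standard_normal(d.data.shape) + 1j * rng.standard_normal(d.data.shape)
        )
    calib = None
    if oversample_calibration:
        d2 = forward_encode(u, profiles, coils, oversampled=True)
        if noise_std > 0:
            d2.data += noise_std * (
                rng.standard_normal(d2.data.shape) + 1j * rng.standard_normal(d2.data.shape)
            )
        calib = calibration_images(d2)
    return d, calib


def calibration_images(d: MultislabKspace) -> np.ndarray:
    """Coil-combined slab images zero-padded to the full FOV.

    Input must be calibration data (2x slice FOV).  Each slab's k-space is
    inverse-transformed and its slices placed at their true z positions;
    slices falling outside the reconstructed FOV are discarded.  Multi-coil
    data are combined by root sum of squares (phase of the first coil kept
    so that profile division remains meaningful for single-coil data).
    """
    if not d.oversampled:
        raise ValueError("calibration requires 2x-FOV oversampled data")
    acq = d.acq
    nz = acq.total_slices
    n_slabs, n_coils, nx, ny, nk = d.data.shape
    out = np.zeros((n_slabs, nx, ny, nz), dtype=complex)
    for s in range(n_slabs):
        z0, period = _kz_window(acq, s, True)
        imgs = np.array([np.fft.ifftn(d.data[s, c], norm="ortho") for c in range(n_coils)])
        if n_coils == 1:
            comb = imgs[0]
        else:
            comb = np.sqrt((np.abs(imgs) ** 2).sum(axis=0))
        for j in range(period):
            z = z0 + j
            if 0 <= z < nz:
                out[s, ..., z] = comb[..., j]
    return out
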