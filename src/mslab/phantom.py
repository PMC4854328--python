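"""Synthetic brain phantom with partial-volume maps.

The phantom stands in for a segmented structural atlas: nested brain-like
compartments (a CSF rim, a cortical GM ribbon, a WM core and CSF
ventricles) with smooth partial-volume transitions, rendered as a
T2-weighted spin-echo image at TE = 78 ms.  It provides known ground truth
for the multislab encoding and reconstruction experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .bloch import TISSUES

__all__ = ["ImageVolume", "PartialVolumeMaps", "make_synthetic_phantom", "t2w_intensity"]

# relative proton density per tissue (water fraction at 3T, approximate)
PROTON_DENSITY = {"WM": 0.70, "GM": 0.85, "CSF": 1.0}


@dataclass
class ImageVolume:
    """A 3D image on an (x, y, z) grid with isotropic-in-plane voxels."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)  # mm

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ImageVolume data must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ImageVolume data must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class PartialVolumeMaps:
    """Per-voxel WM / GM / CSF fractions; background allowed (sum <= 1)."""

    wm: np.ndarray
    gm: np.ndarray
    csf: np.ndarray
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 1.5)

    def __post_init__(self) -> None:
        for name in ("wm", "gm", "csf"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr < -1e-9) or np.any(arr > 1 + 1e-9):
                raise ValueError(f"{name} fractions must lie in [0, 1]")
            setattr(self, name, np.clip(arr, 0.0, 1.0))
        if not (self.wm.shape == self.gm.shape == self.csf.shape):
            raise ValueError("partial volume maps must share a grid")
        if np.any(self.total() > 1 + 1e-6):
            raise ValueError("per-voxel fraction sum must be <= 1")

    def total(self) -> np.ndarray:
        return self.wm + self.gm + self.csf

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"WM": self.wm, "GM": self.gm, "CSF": self.csf}

    def brain_mask(self, threshold: float = 0.5) -> np.ndarray:
        return self.total() > threshold

    def tissue_mask(self, tissue: str, threshold: float = 0.8) -> np.ndarray:
        """Binary segmentation: PV strictly above ``threshold``."""
        return self.as_dict()[tissue.upper()] > threshold


def t2w_intensity(pv: PartialVolumeMaps, te: float = 78.0) -> np.ndarray:
    """T2-weighted signal of a PV mixture: sum of PD * exp(-TE/T2) terms."""
    out = np.zeros_like(pv.wm)
    for name, frac in pv.as_dict().items():
        out += frac * PROTON_DENSITY[name] * np.exp(-te / TISSUES[name].T2)
    return out


def _ellipsoid(grid, center, semiaxes):
    """Soft ellipsoid indicator: 1 inside, 0 outside (hard, smoothed later)."""
    x, y, z = grid
    r = ((x - center[0]) / semiaxes[0]) ** 2
    r += ((y - center[1]) / semiaxes[1]) ** 2
    r += ((z - center[2]) / semiaxes[2]) ** 2
    return (r <= 1.0).astype(float)


def make_synthetic_phantom(
    shape: tuple[int, int, int],
    seed: int = 0,
    te: float = 78.0,
    smooth_vox: float = 1.0,
) -> tuple[ImageVolume, PartialVolumeMaps]:
    """Deterministic brain-like phantom and its WM/GM/CSF fraction maps.

    The geometry is a nested set of ellipsoids: brain envelope, a thin CSF
    rim, a GM ribbon, a WM interior and two CSF ventricles, plus a few
    seeded ellipsoidal GM nuclei inside the WM for structure.  Boundaries
    are smoothed with a Gaussian of ``smooth_vox`` voxels to create
    partial-volume transitions.  Pure-voxel intensities at TE = 78 ms order
    CSF > GM > WM, as dictated by the tissue T2 values.
    """
    nx, ny, nz = shape
    if nx < 32 or ny < 32:
        raise ValueError("in-plane matrix must be at least 32 x 32")
    if nz < 8:
        raise ValueError("need at least 8 slices")
    rng = np.random.default_rng(seed)
    grid = np.meshgrid(
        np.linspace(-1, 1, nx),
        np.linspace(-1, 1, ny),
        np.linspace(-1, 1, nz),
        indexing="ij",
    )

    brain = _ellipsoid(grid, (0, 0, 0), (0.85, 0.9, 0.92))
    inner = _ellipsoid(grid, (0, 0, 0), (0.76, 0.82, 0.84))  # inside CSF rim
    wm_core = _ellipsoid(grid, (0, 0, 0), (0.58, 0.66, 0.68))
    vent_l = _ellipsoid(grid, (-0.18, 0.05, 0.05), (0.10, 0.28, 0.38))
    vent_r = _ellipsoid(grid, (0.18, 0.05, 0.05), (0.10, 0.28, 0.38))
    vents = np.clip(vent_l + vent_r, 0, 1)

    nuclei = np.zeros(shape)
    for _ in range(4):
        c = rng.uniform(-0.35, 0.35, size=3)
        ax = rng.uniform(0.05, 0.12, size=3)
        nuclei = np.clip(nuclei + _ellipsoid(grid, c, ax), 0, 1)

    csf = np.clip(brain - inner, 0, 1) + vents
    gm = np.clip(inner - wm_core, 0, 1) + nuclei * wm_core
    wm = np.clip(wm_core - vents - nuclei * wm_core, 0, 1)
    csf = np.clip(csf, 0, 1)

    sig = smooth_vox
    wm = ndimage.gaussian_filter(wm, sig)
    gm = ndimage.gaussian_filter(gm, sig)
    csf = ndimage.gaussian_filter(csf, sig)
    support = ndimage.gaussian_filter(brain, sig)

    total = wm + gm + csf
    scale = np.where(total > 1e-6, np.minimum(support, total) / np.maximum(total, 1e-6), 0.0)
    wm, gm, csf = wm * scale, gm * scale, csf * scale
    pv = PartialVolumeMaps(wm=wm, gm=gm, csf=csf)

    intensity = t2w_intensity(pv, te=te)
    # mild smooth multiplicative field for texture (deterministic in seed)
    field = ndimage.gaussian_filter(rng.standard_normal(shape), 6.0)
    field = 1.0 + 0.05 * field / max(np.abs(field).max(), 1e-12)
    vol = ImageVolume(data=intensity * field)
    return vol, pv
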