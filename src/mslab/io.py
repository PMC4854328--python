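"""File I/O: NIfTI volumes, HDF5 k-space, CSV profiles, JSON reports."""

from __future__ import annotations

import csv
import json
import os
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .bloch import SignalProfile, SlabAcquisition
from .forward import MultislabKspace
from .phantom import ImageVolume, PartialVolumeMaps
from .pulses import RFPulse

__all__ = [
    "FormatError",
    "save_nifti",
    "load_nifti",
    "save_pv_nifti",
    "load_pv_nifti",
    "save_kspace_h5",
    "load_kspace_h5",
    "save_profile_csv",
    "load_profile_csv",
    "save_profile_nifti",
    "save_pulse_h5",
    "load_pulse_h5",
    "save_json",
    "load_json",
]


class FormatError(ValueError):
    """A file could not be parsed in the expected format."""


def _affine(voxel_size) -> np.ndarray:
    return np.diag([*voxel_size, 1.0])


def save_nifti(vol: ImageVolume | np.ndarray, path, voxel_size=(1.5, 1.5, 1.5)) -> None:
    """Write a volume as NIfTI; complex data are stored as magnitude+phase pair."""
    if isinstance(vol, ImageVolume):
        data, voxel_size = vol.data, vol.voxel_size
    else:
        data = np.asarray(vol)
    if np.iscomplexobj(data):
        data = np.stack([np.abs(data), np.angle(data)], axis=-1)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(voxel_size))
    nib.save(img, str(path))


def load_nifti(path) -> ImageVolume:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
    except Exception as exc:  # nibabel raises several unrelated types
        size = os.path.getsize(path) if os.path.exists(path) else 0
        raise FormatError(f"cannot read NIfTI {path} (file size {size} bytes): {exc}") from exc
    if data.ndim == 4 and data.shape[-1] == 2:  # magnitude+phase pair
        data = data[..., 0] * np.exp(1j * data[..., 1])
    vz = tuple(float(v) for v in img.header.get_zooms()[:3])
    return ImageVolume(data=data, voxel_size=vz)


def save_pv_nifti(pv: PartialVolumeMaps, path) -> None:
    """Write WM/GM/CSF fractions as a 4D NIfTI (last axis = tissue)."""
    data = np.stack([pv.wm, pv.gm, pv.csf], axis=-1)
    nib.save(nib.Nifti1Image(data, _affine(pv.voxel_size)), str(path))


def load_pv_nifti(path) -> PartialVolumeMaps:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise FormatError(f"{path}: expected a 4D WM/GM/CSF fraction volume")
    vz = tuple(float(v) for v in img.header.get_zooms()[:3])
    return PartialVolumeMaps(wm=data[..., 0], gm=data[..., 1], csf=data[..., 2], voxel_size=vz)


_ACQ_FIELDS = ("n_slabs", "slices_per_slab", "slice_thickness", "overlap_slices",
               "TR", "ordering", "TE")


def save_kspace_h5(d: MultislabKspace, path) -> None:
    """HDF5 layout: dataset 'data' (slab, coil, kx, ky, kz) complex + geometry attrs."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("data", data=d.data)
        ds.attrs["oversampled"] = d.oversampled
        ds.attrs["voxel_size"] = d.voxel_size
        for k in _ACQ_FIELDS:
            ds.attrs[k] = getattr(d.acq, k)


def load_kspace_h5(path) -> MultislabKspace:
    try:
        with h5py.File(path, "r") as fh:
            ds = fh["data"]
            data = ds[...]
            attrs = dict(ds.attrs)
    except (OSError, KeyError) as exc:
        size = os.path.getsize(path) if os.path.exists(path) else 0
        raise FormatError(f"cannot read k-space HDF5 {path} "
                          f"(file size {size} bytes): {exc}") from exc
    kw = {k: attrs[k] for k in _ACQ_FIELDS}
    kw["ordering"] = str(kw["ordering"])
    acq = SlabAcquisition(
        n_slabs=int(kw["n_slabs"]), slices_per_slab=int(kw["slices_per_slab"]),
        slice_thickness=float(kw["slice_thickness"]), overlap_slices=int(kw["overlap_slices"]),
        TR=float(kw["TR"]), ordering=kw["ordering"], TE=float(kw["TE"]),
    )
    return MultislabKspace(data=data, acq=acq, oversampled=bool(attrs["oversampled"]),
                           voxel_size=tuple(attrs["voxel_size"]))


def save_profile_csv(profile: SignalProfile, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["slice", "value"])
        w.writerow(["# tissue", profile.tissue])
        w.writerow(["# slab_index", profile.slab_index])
        w.writerow(["# center_slice", profile.center_slice])
        w.writerow(["# normalized", int(profile.normalized)])
        for i, v in enumerate(profile.values):
            w.writerow([i, f"{v:.12e}"])


def load_profile_csv(path) -> SignalProfile:
    meta, vals = {}, []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0] == "slice":
                continue
            if row[0].startswith("#"):
                meta[row[0][1:].strip()] = row[1]
                continue
            vals.append(float(row[1]))
    if not vals:
        raise FormatError(f"{path}: no profile samples")
    return SignalProfile(
        values=np.asarray(vals), tissue=meta.get("tissue", "?"),
        slab_index=int(meta.get("slab_index", 0)),
        center_slice=int(meta.get("center_slice", len(vals) // 2)),
        normalized=bool(int(meta.get("normalized", 0))),
    )


def save_profile_nifti(profile: SignalProfile, path, slice_thickness: float = 1.5) -> None:
    """Store a 1D slab profile as an Nz x 1 x 1 NIfTI volume."""
    data = profile.values.reshape(-1, 1, 1).astype(np.float64)
    nib.save(nib.Nifti1Image(data, _affine((slice_thickness, 1.0, 1.0))), str(path))


def save_pulse_h5(pulse: RFPulse, path) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("samples", data=pulse.samples)
        ds.attrs["dt"] = pulse.dt
        ds.attrs["tbw"] = pulse.tbw
        ds.attrs["nominal_flip"] = pulse.nominal_flip
        ds.attrs["role"] = pulse.role


def load_pulse_h5(path) -> RFPulse:
    try:
        with h5py.File(path, "r") as fh:
            ds = fh["samples"]
            samples = ds[...]
            attrs = dict(ds.attrs)
    except (OSError, KeyError) as exc:
        size = os.path.getsize(path) if os.path.exists(path) else 0
        raise FormatError(f"cannot read pulse HDF5 {path} "
                          f"(file size {size} bytes): {exc}") from exc
    return RFPulse(samples=samples, dt=float(attrs["dt"]), tbw=float(attrs["tbw"]),
                   nominal_flip=float(attrs["nominal_flip"]), role=str(attrs["role"]))


def save_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))


def load_json(path):
    return json.loads(Path(path).read_text())
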