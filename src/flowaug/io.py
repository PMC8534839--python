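"""File I/O: NIfTI and DICOM-series anatomy readers, HDF5 case stores.

Axis convention for all in-memory arrays: (z, y, x), 0-based indices.
NIfTI volumes are reoriented to closest-canonical (RAS) before the
transpose, and the affine is preserved on the returned object; DICOM
series are sorted by slice position with an explicit error on gaps.

HDF5 layouts:
* case store  — ``/dwi_b0``, ``/dwi_b1000`` (complex64, z,y,x), ``/csm``
  (complex64, coil,z,y,x), root attribute ``b_values``.
* k-space export — ``/kspace`` (complex64, coil,z,ky,kx), ``/mask``
  (bool, ky), ``/csm``.
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pydicom

from .augment import CoilSensitivityMaps
from .flow import MagnitudeVolume
from .kspace import KSpaceData, SamplingMask

__all__ = [
    "read_anatomy",
    "write_nifti",
    "write_case",
    "read_case",
    "write_kspace",
    "read_kspace",
]


def read_anatomy(path) -> MagnitudeVolume:
    """Read a magnitude anatomy volume from NIfTI or a DICOM series dir."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        img = nib.as_closest_canonical(nib.load(str(path)))
        data = np.asanyarray(img.dataobj).astype(np.float64)
        if data.ndim != 3:
            raise ValueError(f"expected a 3D NIfTI volume, got {data.ndim}D")
        zooms = img.header.get_zooms()[:3]
        vol = MagnitudeVolume(
            np.clip(np.transpose(data, (2, 1, 0)), 0.0, None),
            voxel_size=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        )
        vol.affine = img.affine  # recorded, not applied
        return vol
    raise ValueError(f"unrecognized anatomy path {path} (need .nii/.nii.gz or DICOM dir)")


def _read_dicom_series(path: Path) -> MagnitudeVolume:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        raise ValueError(f"no DICOM files found in {path}")
    slices = [pydicom.dcmread(str(p)) for p in files]
    try:
        slices.sort(key=lambda d: int(d.InstanceNumber))
        numbers = [int(d.InstanceNumber) for d in slices]
    except AttributeError as e:
        raise ValueError("DICOM slices lack InstanceNumber; cannot order series") from e
    expected = list(range(numbers[0], numbers[0] + len(numbers)))
    if numbers != expected:
        missing = sorted(set(range(numbers[0], numbers[-1] + 1)) - set(numbers))
        raise ValueError(f"DICOM series has gaps at InstanceNumber(s) {missing}")
    data = np.stack([d.pixel_array.astype(np.float64) for d in slices])
    ps = getattr(slices[0], "PixelSpacing", [1.0, 1.0])
    dz = float(getattr(slices[0], "SliceThickness", 1.0))
    return MagnitudeVolume(np.clip(data, 0.0, None), voxel_size=(dz, float(ps[0]), float(ps[1])))


def write_nifti(vol, path, affine=None) -> None:
    """Write a (z, y, x) volume as NIfTI (stored x, y, z)."""
    arr = vol.values if isinstance(vol, MagnitudeVolume) else np.asarray(vol)
    img = nib.Nifti1Image(
        np.transpose(arr, (2, 1, 0)), np.eye(4) if affine is None else affine
    )
    nib.save(img, str(path))


def write_case(path, dwi_b0, dwi_b1000, csm: CoilSensitivityMaps, b_values=(0.0, 1000.0)) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("dwi_b0", data=np.asarray(dwi_b0, np.complex64))
        f.create_dataset("dwi_b1000", data=np.asarray(dwi_b1000, np.complex64))
        f.create_dataset("csm", data=csm.maps.astype(np.complex64))
        f.attrs["b_values"] = np.asarray(b_values, dtype=np.float64)


def read_case(path) -> dict:
    with h5py.File(path, "r") as f:
        return {
            "dwi_b0": f["dwi_b0"][()].astype(np.complex128),
            "dwi_b1000": f["dwi_b1000"][()].astype(np.complex128),
            "csm": CoilSensitivityMaps(f["csm"][()].astype(np.complex128)),
            "b_values": tuple(float(b) for b in f.attrs["b_values"]),
        }


def write_kspace(path, kspace: KSpaceData, mask: SamplingMask, csm: CoilSensitivityMaps) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=kspace.values.astype(np.complex64))
        f.create_dataset("mask", data=mask.lines)
        f.create_dataset("csm", data=csm.maps.astype(np.complex64))
        f.attrs["pattern"] = mask.pattern
        f.attrs["R"] = mask.R
        f.attrs["acs_lines"] = mask.acs_lines


def read_kspace(path) -> tuple[KSpaceData, SamplingMask, CoilSensitivityMaps]:
    with h5py.File(path, "r") as f:
        k = KSpaceData(f["kspace"][()].astype(np.complex128))
        mask = SamplingMask(
            str(f.attrs["pattern"]), float(f.attrs["R"]), int(f.attrs["acs_lines"]), f["mask"][()]
        )
        csm = CoilSensitivityMaps(f["csm"][()].astype(np.complex128))
    return k, mask, csm
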