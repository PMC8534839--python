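"""Flow application to complex multi-coil DWI data and augmentation plans.

Complex data are handled by decomposing into magnitude and phase,
``S = |S| * exp(i*phase)``.  The displacement flow is applied to every
channel (coil-map magnitude and phase, DWI phase), while the intensity
flow touches only the DWI magnitude: ``(S_mag + m*psi) o phi``.  This keeps
coil sensitivities and phase structure physically consistent while varying
anatomy and contrast.

The module also implements the classic in-plane augmentations (shear,
rotation, translation, brightness) and enumerates the six augmentation
group plans used to enlarge a single raw acquisition into a training set.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field as _dc_field
from typing import Iterator, Sequence

import h5py
import numpy as np
from scipy import ndimage

from .flow import (
    DisplacementField,
    IntensityField,
    MagnitudeVolume,
    apply_intensity,
    warp_phase,
    warp_scalar,
)

__all__ = [
    "ComplexVolume",
    "CoilSensitivityMaps",
    "AugmentationPlan",
    "TransformDescriptor",
    "M_LIST_ALT",
    "split_mag_phase",
    "merge_mag_phase",
    "augment_csm",
    "augment_dwi",
    "basic_transform",
    "basic_transform_complex",
    "enumerate_plan",
    "run_plan",
]

#: Alternate intensity-scale list (the methods text quotes two versions).
M_LIST_ALT: tuple[float, ...] = (0.9, 1.1, 1.2, 1.3)


@dataclass
class ComplexVolume:
    """Complex-valued (z, y, x) grid, e.g. a coil-combined DWI volume."""

    values: np.ndarray
    role: str = "dwi"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("complex volume contains non-finite values")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class CoilSensitivityMaps:
    """Per-coil complex sensitivity maps, shape (ncoil, z, y, x)."""

    maps: np.ndarray

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=np.complex128)
        if self.maps.ndim != 4:
            raise ValueError(f"expected (ncoil, z, y, x), got shape {self.maps.shape}")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("coil maps contain non-finite values")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def shape(self):
        return self.maps.shape[1:]

    def rss(self) -> np.ndarray:
        """Root-sum-of-squares magnitude over coils."""
        return np.sqrt((np.abs(self.maps) ** 2).sum(axis=0))


def _cvalues(v) -> np.ndarray:
    if isinstance(v, ComplexVolume):
        return v.values
    return np.asarray(v)


def split_mag_phase(v) -> tuple[np.ndarray, np.ndarray]:
    """Decompose complex data into (magnitude, phase in (-pi, pi])."""
    arr = _cvalues(v)
    mag = np.abs(arr)
    phase = np.angle(arr)
    phase = np.where(phase == -np.pi, np.pi, phase)
    return mag, phase


def merge_mag_phase(mag, phase) -> np.ndarray:
    """Recombine magnitude and phase: ``mag * exp(i*phase)``."""
    mag = np.asarray(mag, dtype=np.float64)
    if mag.min() < 0:
        raise ValueError("magnitude must be non-negative")
    return mag * np.exp(1j * np.asarray(phase, dtype=np.float64))


def augment_csm(csm: CoilSensitivityMaps, field: DisplacementField) -> CoilSensitivityMaps:
    """Warp coil maps by a displacement flow only.

    Magnitude and phase of each coil are warped independently and
    recombined; no intensity flow is ever applied to sensitivities, so the
    coil weighting of the forward model is preserved up to interpolation.
    """
    if csm.shape != field.shape:
        raise ValueError(f"csm grid {csm.shape} != field shape {field.shape}")
    out = np.empty_like(csm.maps)
    for c in range(csm.n_coils):
        mag, ph = split_mag_phase(csm.maps[c])
        out[c] = merge_mag_phase(
            np.clip(warp_scalar(mag, field), 0.0, None), warp_phase(ph, field)
        )
    return CoilSensitivityMaps(out)


def augment_dwi(dwi, field: DisplacementField, psi, m: float = 1.0) -> np.ndarray:
    """Apply intensity then displacement flow to a complex DWI volume.

    The phase channel is displacement-warped only; the magnitude first
    receives the scaled additive intensity flow and is then warped:
    ``out = clip(|S| + m*psi, 0) o phi * exp(i * (angle(S) o phi))``.
    """
    arr = _cvalues(dwi)
    p = psi.psi if isinstance(psi, IntensityField) else np.asarray(psi)
    if arr.shape != field.shape or p.shape != field.shape:
        raise ValueError("dwi / field / psi shapes differ")
    mag, ph = split_mag_phase(arr)
    shifted = mag + m * p
    neg_frac = float((shifted < 0).mean())
    if neg_frac > 0.10:
        warnings.warn(
            f"intensity flow drove {neg_frac:.0%} of magnitudes negative (clipped)",
            RuntimeWarning,
            stacklevel=2,
        )
    mag_aug = warp_scalar(np.clip(shifted, 0.0, None), field)
    ph_aug = warp_phase(ph, field)
    return merge_mag_phase(np.clip(mag_aug, 0.0, None), ph_aug)


# ---------------------------------------------------------------------------
# basic (affine + brightness) augmentations
# ---------------------------------------------------------------------------

def _inplane_affine(vol: np.ndarray, matrix: np.ndarray, offset_center=True) -> np.ndarray:
    """Apply a 2x2 in-plane (y, x) affine about the slice center, slice-wise."""
    out = np.empty_like(vol, dtype=np.float64)
    center = (np.array(vol.shape[1:]) - 1) / 2.0
    # affine_transform uses pull mapping: input_coord = matrix @ output + offset
    offset = center - matrix @ center
    for z in range(vol.shape[0]):
        out[z] = ndimage.affine_transform(
            vol[z].astype(np.float64), matrix, offset=offset, order=1, mode="constant", cval=0.0
        )
    return out


def basic_transform(vol, kind: str, parameter):
    """Classic slice-wise augmentation of a real-valued volume.

    kind:
      - ``"shear"``: in-plane shear, x displaced by ``parameter * y``.
      - ``"rotate"``: in-plane rotation, degrees counter-clockwise.
      - ``"translate"``: ``(tx, ty)`` pixel shift along x and y.
      - ``"brightness"``: global multiplicative intensity scale.
    """
    arr = np.asarray(vol, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError("expected a 3D (z, y, x) volume")
    if kind == "brightness":
        return arr * float(parameter)
    if kind == "shear":
        m = np.array([[1.0, 0.0], [float(parameter), 1.0]])  # x' = x + s*y (pull)
        return _inplane_affine(arr, m)
    if kind == "rotate":
        th = np.deg2rad(float(parameter))
        m = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return _inplane_affine(arr, m)
    if kind == "translate":
        tx, ty = (float(p) for p in parameter)
        out = np.empty_like(arr)
        for z in range(arr.shape[0]):
            out[z] = ndimage.shift(arr[z], (ty, tx), order=1, mode="constant", cval=0.0)
        return out
    raise ValueError(f"unknown transform kind {kind!r}")


def basic_transform_complex(values: np.ndarray, kind: str, parameter) -> np.ndarray:
    """Apply a basic transform to complex data via magnitude/cos/sin channels.

    Brightness scales magnitude only; geometric kinds resample all three
    channels identically so DWI, phase and coil maps stay consistent.
    """
    mag, ph = split_mag_phase(values)
    if kind == "brightness":
        return merge_mag_phase(mag * float(parameter), ph)
    mag_t = np.clip(basic_transform(mag, kind, parameter), 0.0, None)
    c_t = basic_transform(np.cos(ph), kind, parameter)
    s_t = basic_transform(np.sin(ph), kind, parameter)
    return merge_mag_phase(mag_t, np.arctan2(s_t, c_t))


# ---------------------------------------------------------------------------
# augmentation plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransformDescriptor:
    """One augmented case: an ordered tuple of (kind, parameter) basic ops
    plus optional flow indices (geometry target i, intensity target j, scale m)."""

    ops: tuple = ()
    geometry_index: int | None = None
    intensity_index: int | None = None
    m: float | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "ops": [[k, p] for k, p in self.ops],
                "geometry_index": self.geometry_index,
                "intensity_index": self.intensity_index,
                "m": self.m,
            }
        )


@dataclass
class AugmentationPlan:
    """Parameter lists and group selector for one augmentation campaign.

    Groups: ``s`` shear x brightness; ``r`` rotation x brightness; ``t``
    translation x brightness; ``srt`` shear x rotation x translation x
    brightness; ``d`` learned geometry targets x brightness x translation;
    ``di`` learned geometry x intensity targets x intensity scale m.
    """

    group: str
    shear_list: tuple[float, ...] = (0.05, 0.10, -0.05, -0.10)
    rotation_list: tuple[float, ...] = (20, 40, 60, 80, 100, 120, 140, 160)
    translation_x_list: tuple[float, ...] = (12, -12, 24, -24)
    translation_y_list: tuple[float, ...] = (12, -12, 24, -24)
    brightness_list: tuple[float, ...] = (0.8, 0.9, 1.0, 1.1, 1.2)
    n_geometry_targets: int = 26
    n_intensity_targets: int = 26
    m_list: tuple[float, ...] = (0.8, 0.9, 1.1, 1.2)
    include_displacement_only: bool = False

    GROUPS = ("s", "r", "t", "srt", "d", "di")

    def __post_init__(self):
        if self.group not in self.GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {self.GROUPS}")

    def _translations(self):
        # x and y lists form a full Cartesian grid of (tx, ty) shifts
        return [(tx, ty) for tx in self.translation_x_list for ty in self.translation_y_list]

    def count(self) -> int:
        n_t = len(self.translation_x_list) * len(self.translation_y_list)
        n_b = len(self.brightness_list)
        if self.group == "s":
            return len(self.shear_list) * n_b
        if self.group == "r":
            return len(self.rotation_list) * n_b
        if self.group == "t":
            return n_t * n_b
        if self.group == "srt":
            return len(self.shear_list) * len(self.rotation_list) * n_t * n_b
        if self.group == "d":
            return self.n_geometry_targets * n_b * n_t
        n = self.n_geometry_targets * self.n_intensity_targets * len(self.m_list)
        if self.include_displacement_only:
            n += self.n_geometry_targets
        return n

    def needs_flows(self) -> bool:
        return self.group in ("d", "di")


def enumerate_plan(plan: AugmentationPlan) -> Iterator[TransformDescriptor]:
    """Lazily yield the full Cartesian product of a plan's descriptors.

    The order is deterministic (lexicographic over the plan's lists, in the
    order the group definition states).  ``plan.count()`` gives the total
    without materializing the sequence.
    """
    g = plan.group
    if g in ("s", "r", "t", "srt") and not plan.brightness_list:
        raise ValueError("brightness_list must be non-empty")
    if g == "s":
        for s, b in itertools.product(plan.shear_list, plan.brightness_list):
            yield TransformDescriptor(ops=(("shear", s), ("brightness", b)))
    elif g == "r":
        for r, b in itertools.product(plan.rotation_list, plan.brightness_list):
            yield TransformDescriptor(ops=(("rotate", r), ("brightness", b)))
    elif g == "t":
        for t, b in itertools.product(plan._translations(), plan.brightness_list):
            yield TransformDescriptor(ops=(("translate", t), ("brightness", b)))
    elif g == "srt":
        for s, r, t, b in itertools.product(
            plan.shear_list, plan.rotation_list, plan._translations(), plan.brightness_list
        ):
            yield TransformDescriptor(
                ops=(("shear", s), ("rotate", r), ("translate", t), ("brightness", b))
            )
    elif g == "d":
        for i, b, t in itertools.product(
            range(plan.n_geometry_targets), plan.brightness_list, plan._translations()
        ):
            yield TransformDescriptor(
                ops=(("brightness", b), ("translate", t)), geometry_index=i
            )
    else:  # di
        if plan.include_displacement_only:
            for i in range(plan.n_geometry_targets):
                yield TransformDescriptor(geometry_index=i)
        for i, j, m in itertools.product(
            range(plan.n_geometry_targets), range(plan.n_intensity_targets), plan.m_list
        ):
            yield TransformDescriptor(geometry_index=i, intensity_index=j, m=m)


def _apply_descriptor(case: dict, desc: TransformDescriptor, flows) -> dict:
    """Produce one augmented case {'dwi_b0', 'dwi_b1000', 'csm'} from a source."""
    b0 = _cvalues(case["dwi_b0"]).copy()
    b1 = _cvalues(case["dwi_b1000"]).copy()
    csm = case["csm"] if isinstance(case["csm"], CoilSensitivityMaps) else CoilSensitivityMaps(case["csm"])

    if desc.geometry_index is not None:
        phi, psi = flows[desc.geometry_index]
        if desc.intensity_index is not None:
            psi_j = flows[desc.intensity_index][1]
            m = desc.m if desc.m is not None else 1.0
        else:
            psi_j, m = np.zeros(phi.shape), 1.0
        b0 = augment_dwi(b0, phi, psi_j, m)
        b1 = augment_dwi(b1, phi, psi_j, m)
        csm = augment_csm(csm, phi)

    for kind, param in desc.ops:
        b0 = basic_transform_complex(b0, kind, param)
        b1 = basic_transform_complex(b1, kind, param)
        if kind != "brightness":  # coil sensitivities keep their intensities
            csm = CoilSensitivityMaps(
                np.stack([basic_transform_complex(csm.maps[c], kind, param) for c in range(csm.n_coils)])
            )
    return {"dwi_b0": b0, "dwi_b1000": b1, "csm": csm}


def run_plan(plan: AugmentationPlan, source_case: dict, flows, out_path) -> int:
    """Stream every augmented case of ``plan`` into an HDF5 store.

    ``source_case`` maps 'dwi_b0'/'dwi_b1000' to complex volumes and 'csm'
    to coil maps.  ``flows`` is a sequence of (DisplacementField,
    IntensityField-or-array) pairs indexed by target; required (and checked)
    for groups that apply learned flows.  Returns the number of cases
    written; layout is ``/case_NNNNN/{dwi_b0,dwi_b1000,csm}`` (complex64)
    with the descriptor recorded as a provenance attribute.
    """
    flows = list(flows) if flows is not None else []
    n_targets_needed = plan.n_geometry_targets if plan.needs_flows() else 0
    if plan.needs_flows() and len(flows) < max(n_targets_needed, plan.n_intensity_targets if plan.group == "di" else 0):
        raise ValueError(
            f"group {plan.group!r} needs flows for {n_targets_needed} targets, got {len(flows)}"
        )
    flows = [
        (phi, psi.psi if isinstance(psi, IntensityField) else np.asarray(psi))
        for phi, psi in flows
    ]
    n = 0
    with h5py.File(out_path, "w") as f:
        f.attrs["group"] = plan.group
        for idx, desc in enumerate(enumerate_plan(plan)):
            case = _apply_descriptor(source_case, desc, flows)
            grp = f.create_group(f"case_{idx:05d}")
            grp.create_dataset("dwi_b0", data=case["dwi_b0"].astype(np.complex64))
            grp.create_dataset("dwi_b1000", data=case["dwi_b1000"].astype(np.complex64))
            grp.create_dataset("csm", data=case["csm"].maps.astype(np.complex64))
            grp.attrs["descriptor"] = desc.to_json()
            grp.attrs["geometry_index"] = -1 if desc.geometry_index is None else desc.geometry_index
            grp.attrs["intensity_index"] = -1 if desc.intensity_index is None else desc.intensity_index
            grp.attrs["m"] = np.nan if desc.m is None else desc.m
            n += 1
    assert n == plan.count()
    return n
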