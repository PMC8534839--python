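"""Synthetic phantom generator: anatomy pairs with known flows, coil maps
and diffusion-weighted volumes.

The generator provides every input the augmentation pipeline consumes, with
ground truth attached so flow learning and ADC fitting can be validated by
parameter recovery:

* brain-like anatomy as nested smooth ellipsoidal tissue compartments;
* subject pairs related by a known smooth displacement field and a known
  additive intensity field (``target = (source + psi) o phi``);
* smooth complex coil sensitivity maps, RSS-normalized;
* complex DWI volumes at b=0 and b=b_value obeying the mono-exponential
  decay ``S_b / S_0 = exp(-b * ADC)`` voxel-wise, sharing one smooth
  synthetic phase map.

All outputs are pure functions of (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .augment import CoilSensitivityMaps, merge_mag_phase
from .flow import DisplacementField, IntensityField, MagnitudeVolume, warp_scalar

__all__ = [
    "PhantomSpec",
    "GroundTruthBundle",
    "DWICase",
    "make_brain_phantom",
    "make_coil_maps",
    "make_subject_pair",
    "make_dwi_case",
    "TISSUE_ADC",
]

#: Default per-tissue apparent diffusion coefficients (mm^2/s), cycled over
#: tissue labels 1..n.  Values span the physiological range: white matter
#: ~0.7e-3, grey matter ~0.9e-3, oedema ~1.3e-3, CSF ~3.0e-3.
TISSUE_ADC: tuple[float, ...] = (0.7e-3, 0.9e-3, 1.3e-3, 3.0e-3, 1.0e-3, 2.0e-3)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic study conditions.

    grid_shape is (nz, ny, nx) voxels; deform_amplitude is the mean endpoint
    length of the ground-truth displacement (voxels); deform_smoothness the
    Gaussian kernel width used to smooth the random fields (voxels);
    intensity_amplitude the RMS of the intensity field as a fraction of the
    mean source intensity; noise_sigma the Gaussian noise level on the
    [0, 1]-scaled intensities; b_value in s/mm^2.
    """

    grid_shape: tuple[int, int, int] = (16, 64, 64)
    n_tissues: int = 3
    n_coils: int = 8
    deform_amplitude: float = 2.0
    deform_smoothness: float = 6.0
    intensity_amplitude: float = 0.10
    noise_sigma: float = 0.0
    b_value: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(int(s) < 8 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 components, each >= 8")
        if self.n_tissues < 1 or self.n_coils < 1:
            raise ValueError("n_tissues and n_coils must be >= 1")
        if self.deform_smoothness <= 0:
            raise ValueError("deform_smoothness must be positive")
        if self.deform_amplitude < 0 or self.intensity_amplitude < 0 or self.noise_sigma < 0:
            raise ValueError("amplitudes and noise_sigma must be non-negative")
        if self.b_value < 0:
            raise ValueError("b_value must be non-negative")


@dataclass
class GroundTruthBundle:
    """A source/target anatomy pair with its generating flows and ADC map."""

    source: MagnitudeVolume
    target: MagnitudeVolume
    true_displacement: DisplacementField
    true_intensity: IntensityField
    true_adc: np.ndarray
    labels: np.ndarray


@dataclass
class DWICase:
    """Complex DWI volumes at b=0 and b=b_value with ground-truth ADC."""

    b0: np.ndarray
    dwi: np.ndarray
    b_value: float
    true_adc: np.ndarray
    phase: np.ndarray


def _normalized_coords(shape):
    """Per-axis coordinates in [-1, 1] about the grid center."""
    return np.meshgrid(
        *[np.linspace(-1.0, 1.0, s) for s in shape], indexing="ij"
    )


def make_brain_phantom(spec: PhantomSpec, seed: int | None = None):
    """Build a nested-ellipsoid anatomy volume and its tissue label grid.

    Tissue label 0 is background; labels 1..n_tissues are concentric
    compartments (innermost = n_tissues) with seeded per-tissue intensities
    in [0.3, 1.0].  With several tissues the compartment boundaries are
    perturbed by a smooth random field so the anatomy is not perfectly
    symmetric.  Noise (if any) rides on a small positive pedestal so the
    volume stays non-negative while the background sample standard
    deviation matches ``noise_sigma``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    shape = tuple(int(s) for s in spec.grid_shape)
    zc, yc, xc = _normalized_coords(shape)
    # head ellipsoid: slightly anisotropic, off-center to break symmetry
    semi = np.array([0.80, 0.72, 0.78])
    r = np.sqrt((zc / semi[0]) ** 2 + (yc / semi[1]) ** 2 + (xc / semi[2]) ** 2)
    if spec.n_tissues > 1:
        bump = rng.standard_normal(shape)
        bump = ndimage.gaussian_filter(bump, sigma=[max(2.0, s / 10) for s in shape])
        bump /= max(np.abs(bump).max(), 1e-12)
        r = r + 0.08 * bump
    labels = np.zeros(shape, dtype=np.int32)
    inside = r < 1.0
    # concentric shells: innermost gets the highest label
    shell = np.clip((r * spec.n_tissues).astype(np.int32), 0, spec.n_tissues - 1)
    labels[inside] = (spec.n_tissues - shell)[inside]
    intensities = np.concatenate([[0.0], rng.uniform(0.3, 1.0, size=spec.n_tissues)])
    vol = intensities[labels]
    if spec.n_tissues > 1:
        # smooth intra-tissue texture: real anatomy is not piecewise constant,
        # and texture keeps the flow identifiable away from tissue boundaries
        tex = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=3.0)
        tex /= max(np.abs(tex).max(), 1e-12)
        vol = np.clip(vol * (1.0 + 0.2 * tex), 0.0, None)
    if spec.noise_sigma > 0:
        vol = vol + 6.0 * spec.noise_sigma + rng.normal(0.0, spec.noise_sigma, size=shape)
        vol = np.clip(vol, 0.0, None)
    return MagnitudeVolume(vol), labels


def make_coil_maps(spec: PhantomSpec, seed: int | None = None) -> CoilSensitivityMaps:
    """Smooth complex coil maps: Gaussian magnitude lobes on a ring of
    virtual coils around the in-plane center, low-order polynomial phase.

    Maps are normalized by their root-sum-of-squares, so RSS == 1
    everywhere and each coil magnitude is <= 1.  A single coil degenerates
    to constant unit magnitude with zero phase.
    """
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 101)
    shape = tuple(int(s) for s in spec.grid_shape)
    if spec.n_coils == 1:
        return CoilSensitivityMaps(np.ones((1, *shape), dtype=np.complex128))
    zc, yc, xc = _normalized_coords(shape)
    maps = np.empty((spec.n_coils, *shape), dtype=np.complex128)
    angles = 2 * np.pi * np.arange(spec.n_coils) / spec.n_coils
    for c, th in enumerate(angles):
        cy, cx = 1.1 * np.sin(th), 1.1 * np.cos(th)
        d2 = (yc - cy) ** 2 + (xc - cx) ** 2 + 0.15 * zc ** 2
        mag = np.exp(-d2 / (2 * 0.8 ** 2))
        coef = rng.uniform(-0.6, 0.6, size=5)
        phase = coef[0] + coef[1] * yc + coef[2] * xc + coef[3] * zc + coef[4] * yc * xc
        maps[c] = mag * np.exp(1j * phase)
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    return CoilSensitivityMaps(maps / rss)


def _smooth_noise(rng, shape, sigma):
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    return field


def make_subject_pair(spec: PhantomSpec, seed: int) -> GroundTruthBundle:
    """Generate a (source, target) anatomy pair with known generating flows.

    The displacement is Gaussian-smoothed white noise scaled so the mean
    endpoint length equals ``deform_amplitude`` voxels; the intensity field
    is smoothed noise with RMS ``intensity_amplitude * mean(source)``.  The
    target is constructed exactly as ``(source + psi) o phi``, so the pair's
    ground truth is exact by construction.  Fields steep enough to fold the
    grid are rejected.
    """
    rng = np.random.default_rng(seed)
    source, labels = make_brain_phantom(spec, seed=spec.seed)
    shape = source.shape
    if spec.deform_amplitude > 0:
        u = np.stack([_smooth_noise(rng, shape, spec.deform_smoothness) for _ in range(3)])
        epl = np.sqrt((u ** 2).sum(axis=0)).mean()
        u *= spec.deform_amplitude / max(epl, 1e-12)
    else:
        u = np.zeros((3, *shape))
        rng.standard_normal((3, *shape))  # keep stream position stable
    grad = max(
        (np.abs(np.diff(u[d], axis=d)).max() if shape[d] > 1 else 0.0) for d in range(3)
    )
    if grad >= 1.0:
        raise ValueError(
            f"deform_amplitude/smoothness produce a folding field (max grad {grad:.2f})"
        )
    phi = DisplacementField(u)
    mean_src = float(source.values[labels > 0].mean()) if (labels > 0).any() else float(
        source.values.mean()
    )
    if spec.intensity_amplitude > 0:
        psi = _smooth_noise(rng, shape, spec.deform_smoothness)
        psi *= spec.intensity_amplitude * mean_src / max(np.sqrt((psi ** 2).mean()), 1e-12)
        psi *= labels > 0  # contrast changes live inside the anatomy
    else:
        psi = np.zeros(shape)
        rng.standard_normal(shape)
    target_vals = np.clip(warp_scalar(np.clip(source.values + psi, 0, None), phi), 0.0, None)
    adc = _adc_map(labels)
    return GroundTruthBundle(
        source=source,
        target=MagnitudeVolume(target_vals),
        true_displacement=phi,
        true_intensity=IntensityField(psi),
        true_adc=adc,
        labels=labels,
    )


def _adc_map(labels: np.ndarray) -> np.ndarray:
    adc = np.zeros(labels.shape)
    for lab in range(1, labels.max() + 1):
        adc[labels == lab] = TISSUE_ADC[(lab - 1) % len(TISSUE_ADC)]
    return adc


def make_dwi_case(
    spec: PhantomSpec,
    anatomy: MagnitudeVolume,
    labels: np.ndarray,
    csm: CoilSensitivityMaps | None = None,
    seed: int | None = None,
) -> DWICase:
    """Synthesize complex DWI volumes from an anatomy volume.

    The b=0 magnitude is the anatomy; the diffusion-weighted magnitude is
    attenuated voxel-wise by ``exp(-b * ADC)`` with per-tissue ADC values.
    Both volumes share one smooth phase map (low-order polynomial plus a
    smoothed random component).  Complex Gaussian noise with standard
    deviation ``noise_sigma`` per channel is added after the forward model,
    so the noiseless case inverts exactly.
    """
    if spec.b_value < 0:
        raise ValueError("b_value must be non-negative")
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 202)
    shape = anatomy.shape
    zc, yc, xc = _normalized_coords(shape)
    coef = rng.uniform(-1.0, 1.0, size=6)
    phase = (
        coef[0]
        + coef[1] * yc
        + coef[2] * xc
        + coef[3] * zc
        + coef[4] * yc * xc
        + coef[5] * (yc ** 2 - xc ** 2)
    )
    phase = phase + 0.4 * _smooth_noise(rng, shape, 4.0)
    adc = _adc_map(labels)
    mag0 = anatomy.values
    magb = mag0 * np.exp(-spec.b_value * adc)
    b0 = merge_mag_phase(mag0, phase)
    dwi = merge_mag_phase(magb, phase)
    if spec.noise_sigma > 0:
        b0 = b0 + spec.noise_sigma * (
            rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        )
        dwi = dwi + spec.noise_sigma * (
            rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        )
    return DWICase(b0=b0, dwi=dwi, b_value=spec.b_value, true_adc=adc, phase=phase)
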