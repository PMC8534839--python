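"""Multi-coil Cartesian k-space simulation, undersampling and reconstruction.

The forward model is 2D and slice-wise: each coil image is the product of
the coil sensitivity and the underlying complex image; k-space is its
centered, unitary 2D Fourier transform; undersampling selects phase-encode
lines (the y axis).  Reconstruction is either zero-filling with
conjugate-sensitivity combination or CG-SENSE — conjugate gradients on the
normal equations ``E^H E x = E^H y`` of the masked multi-coil Fourier
operator ``E``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augment import CoilSensitivityMaps

__all__ = [
    "KSpaceData",
    "SamplingMask",
    "fft2c",
    "ifft2c",
    "image_to_kspace",
    "kspace_to_coil_images",
    "apply_mask",
    "make_uniform_mask",
    "make_vd_mask",
    "cg_sense_recon",
    "zero_filled_recon",
    "estimate_csm_lowres",
]


def fft2c(x: np.ndarray) -> np.ndarray:
    """Centered, unitary 2D FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)), axes=(-2, -1), norm="ortho"),
        axes=(-2, -1),
    )


def ifft2c(x: np.ndarray) -> np.ndarray:
    """Centered, unitary 2D inverse FFT over the last two axes."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=(-2, -1)), axes=(-2, -1), norm="ortho"),
        axes=(-2, -1),
    )


@dataclass
class KSpaceData:
    """Multi-coil k-space, shape (ncoil, nz, ky, kx), DC at the center."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 4:
            raise ValueError(f"expected (ncoil, nz, ky, kx), got {self.values.shape}")

    @property
    def n_coils(self) -> int:
        return self.values.shape[0]


@dataclass
class SamplingMask:
    """Cartesian line-selection mask along the phase-encode (ky) axis."""

    pattern: str
    R: float
    acs_lines: int
    lines: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        self.lines = np.asarray(self.lines, dtype=bool)
        if self.lines.ndim != 1:
            raise ValueError("lines must be a 1D boolean array over ky")

    @property
    def n_sampled(self) -> int:
        return int(self.lines.sum())


def image_to_kspace(img, csm: CoilSensitivityMaps) -> KSpaceData:
    """Forward SENSE model: per-coil k-space of csm-weighted images."""
    arr = np.asarray(img.values if hasattr(img, "values") else img, dtype=np.complex128)
    if arr.shape != csm.shape:
        raise ValueError(f"image shape {arr.shape} != csm grid {csm.shape}")
    return KSpaceData(fft2c(csm.maps * arr[None]))


def kspace_to_coil_images(kspace: KSpaceData) -> np.ndarray:
    return ifft2c(kspace.values)


def apply_mask(kspace: KSpaceData, mask: SamplingMask) -> KSpaceData:
    if kspace.values.shape[2] != mask.lines.size:
        raise ValueError("mask length does not match ky dimension")
    return KSpaceData(kspace.values * mask.lines[None, None, :, None])


def make_uniform_mask(n_lines: int, R: int, acs_lines: int = 0) -> SamplingMask:
    """Every R-th phase-encode line, phased through DC, plus a centered
    fully-sampled ACS block."""
    if R < 1 or int(R) != R:
        raise ValueError("R must be a positive integer")
    if acs_lines < 0 or acs_lines >= n_lines:
        raise ValueError("acs_lines must be in [0, n_lines)")
    idx = np.arange(n_lines)
    lines = (idx - n_lines // 2) % int(R) == 0
    if acs_lines:
        start = n_lines // 2 - acs_lines // 2
        lines[start : start + acs_lines] = True
    return SamplingMask("uniform", float(R), acs_lines, lines)


def make_vd_mask(
    n_lines: int,
    R: float,
    acs_lines: int = 0,
    density_exponent: float = 2.0,
    seed: int = 0,
) -> SamplingMask:
    """Variable-density mask: ACS block always sampled, remaining lines
    drawn without replacement with probability ~ (1 - |ky|/kmax)^exponent.

    The total sampled count is round(n_lines / R); deterministic per seed.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    budget = int(round(n_lines / R))
    if acs_lines > budget:
        raise ValueError(f"acs_lines ({acs_lines}) exceeds the sampling budget ({budget})")
    lines = np.zeros(n_lines, dtype=bool)
    start = n_lines // 2 - acs_lines // 2
    lines[start : start + acs_lines] = True
    remaining = budget - int(lines.sum())
    ky = np.arange(n_lines) - n_lines // 2
    kmax = np.abs(ky).max()
    # +1 keeps the outermost line drawable, so a full budget (R -> 1) is feasible
    p = (1.0 - np.abs(ky) / (kmax + 1.0)) ** density_exponent
    p[lines] = 0.0
    if remaining > 0:
        rng = np.random.default_rng(seed)
        if p.sum() <= 0:
            raise ValueError("density law leaves no candidate lines")
        chosen = rng.choice(n_lines, size=remaining, replace=False, p=p / p.sum())
        lines[chosen] = True
    return SamplingMask("variable_density", float(R), acs_lines, lines, seed=seed)


def _sense_normal_op(x: np.ndarray, csm: np.ndarray, lines: np.ndarray) -> np.ndarray:
    """E^H E applied to an image x, for the masked multi-coil operator."""
    k = fft2c(csm * x[None]) * lines[None, None, :, None]
    return (np.conj(csm) * ifft2c(k)).sum(axis=0)


class CGDivergenceError(RuntimeError):
    pass


def cg_sense_recon(
    kspace: KSpaceData,
    csm: CoilSensitivityMaps,
    mask: SamplingMask,
    max_iters: int = 30,
    tol: float = 1e-6,
):
    """CG-SENSE: conjugate-gradient solution of ``E^H E x = E^H y``.

    Returns ``(image, residuals)`` where residuals is the per-iteration
    relative normal-equation residual ``||b - E^H E x|| / ||b||``.  Raises
    :class:`CGDivergenceError` if the residual grows for 10 consecutive
    iterations.
    """
    masked = apply_mask(kspace, mask)
    b = (np.conj(csm.maps) * ifft2c(masked.values)).sum(axis=0)
    bnorm = np.linalg.norm(b)
    if bnorm == 0:
        return np.zeros_like(b), [0.0]
    x = np.zeros_like(b)
    r = b.copy()
    p = r.copy()
    rs = np.vdot(r, r).real
    residuals = [float(np.sqrt(rs) / bnorm)]
    grow_count = 0
    for _ in range(max_iters):
        if residuals[-1] <= tol:
            break
        ap = _sense_normal_op(p, csm.maps, mask.lines)
        alpha = rs / max(np.vdot(p, ap).real, 1e-300)
        x = x + alpha * p
        r = r - alpha * ap
        rs_new = np.vdot(r, r).real
        residuals.append(float(np.sqrt(rs_new) / bnorm))
        grow_count = grow_count + 1 if residuals[-1] > residuals[-2] else 0
        if grow_count >= 10:
            raise CGDivergenceError(
                f"CG residual grew for 10 consecutive iterations (last {residuals[-1]:.3g})"
            )
        p = r + (rs_new / max(rs, 1e-300)) * p
        rs = rs_new
    return x, residuals


def zero_filled_recon(kspace: KSpaceData, csm: CoilSensitivityMaps, mask: SamplingMask):
    """Inverse transform of the masked data, conjugate-sensitivity combined.

    ``x = sum_c conj(S_c) x_c / sum_c |S_c|^2`` — equal to the CG-SENSE
    solution when the mask is full.
    """
    coil_imgs = ifft2c(apply_mask(kspace, mask).values)
    num = (np.conj(csm.maps) * coil_imgs).sum(axis=0)
    den = (np.abs(csm.maps) ** 2).sum(axis=0)
    return np.where(den > 1e-12, num / np.where(den > 1e-12, den, 1.0), 0.0)


def estimate_csm_lowres(kspace: KSpaceData, acs_lines: int) -> CoilSensitivityMaps:
    """Low-resolution coil-map estimate from the central k-space block.

    The central ``acs_lines`` phase-encode lines are apodized with a Hamming
    window, inverse-transformed, and normalized by their root-sum-of-squares,
    giving maps with RSS == 1 on the image support.
    """
    if acs_lines < 8:
        raise ValueError("at least 8 ACS lines are required")
    n_ky = kspace.values.shape[2]
    win = np.zeros(n_ky)
    start = n_ky // 2 - acs_lines // 2
    win[start : start + acs_lines] = np.hamming(acs_lines)
    low = ifft2c(kspace.values * win[None, None, :, None])
    rss = np.sqrt((np.abs(low) ** 2).sum(axis=0))
    support = rss > 0.05 * rss.max()
    maps = np.where(support[None], low / np.where(support, rss, 1.0)[None], 0.0)
    return CoilSensitivityMaps(maps)
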