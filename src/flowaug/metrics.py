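"""Reconstruction quality metrics and ADC map fitting.

PSNR and SSIM follow the standard definitions (SSIM with the Gaussian
11x11, sigma 1.5 window and k1=0.01, k2=0.03 constants); the apparent
diffusion coefficient is fitted voxel-wise from the two-point
mono-exponential model ``S_b / S_0 = exp(-b * ADC)``, and masking is a
threshold + largest-connected-component brain mask standing in for a full
skull-stripping tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

from .flow import MagnitudeVolume

__all__ = ["MetricReport", "psnr", "ssim", "mse", "fit_adc", "brain_mask", "evaluate_pair"]


@dataclass
class MetricReport:
    psnr: float
    ssim: float
    mse: float
    n_voxels: int
    mask_description: str = "whole image"


def _arr(x) -> np.ndarray:
    return x.values if isinstance(x, MagnitudeVolume) else np.asarray(x, dtype=np.float64)


def mse(ref, test, mask=None) -> float:
    r, t = _arr(ref), _arr(test)
    if r.shape != t.shape:
        raise ValueError("shape mismatch")
    d = (r - t) ** 2
    return float(d[mask].mean() if mask is not None else d.mean())


def psnr(ref, test, data_range: float | None = None, mask=None) -> float:
    """Peak signal-to-noise ratio, ``10 log10(data_range^2 / MSE)`` in dB.

    ``data_range`` defaults to the maximum of the reference.  Identical
    inputs return the +inf sentinel.
    """
    r = _arr(ref)
    err = mse(ref, test, mask=mask)
    if err == 0.0:
        return math.inf
    if data_range is None:
        data_range = float(r.max())
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    return float(10.0 * np.log10(data_range ** 2 / err))


def ssim(ref, test, data_range: float | None = None, mask=None) -> float:
    """Mean structural similarity with the standard Gaussian window.

    3D volumes are scored slice-wise in the axial (y, x) plane — the plane
    the slice-wise reconstruction operates in — and averaged.  When a mask
    is given, the local SSIM map is averaged over the mask only (mirroring
    evaluation inside a brain mask after skull stripping).
    """
    r, t = _arr(ref), _arr(test)
    if r.shape != t.shape:
        raise ValueError("shape mismatch")
    if data_range is None:
        data_range = float(r.max() - r.min())
        if data_range == 0:
            data_range = 1.0
    kwargs = dict(
        data_range=data_range,
        gaussian_weights=True,
        sigma=1.5,
        win_size=11,
        use_sample_covariance=False,
        K1=0.01,
        K2=0.03,
    )
    if min(r.shape[-2:]) < 11:
        raise ValueError("in-plane extent smaller than the 11-voxel SSIM window")
    if r.ndim == 2:
        planes = [(r, t, None if mask is None else np.asarray(mask, bool))]
    else:
        m = None if mask is None else np.asarray(mask, bool)
        planes = [(r[z], t[z], None if m is None else m[z]) for z in range(r.shape[0])]
    vals, weights = [], []
    for rp, tp, mp in planes:
        if mp is None:
            vals.append(float(structural_similarity(rp, tp, **kwargs)))
            weights.append(rp.size)
        else:
            if not mp.any():
                continue
            _, smap = structural_similarity(rp, tp, full=True, **kwargs)
            vals.append(float(smap[mp].mean()))
            weights.append(int(mp.sum()))
    if not vals:
        raise ValueError("mask is empty")
    return float(np.average(vals, weights=weights))


def fit_adc(s0, sb, b: float, mask=None) -> np.ndarray:
    """Voxel-wise mono-exponential ADC fit: ``ADC = -ln(S_b/S_0) / b``.

    Units follow b (s/mm^2 gives mm^2/s).  Voxels with non-positive signal
    in either volume (or outside the mask) are set to NaN.
    """
    if b <= 0:
        raise ValueError("b must be positive")
    a0, ab = _arr(s0), _arr(sb)
    if a0.shape != ab.shape:
        raise ValueError("shape mismatch")
    valid = (a0 > 0) & (ab > 0)
    if mask is not None:
        valid &= np.asarray(mask, bool)
    adc = np.full(a0.shape, np.nan)
    adc[valid] = -np.log(ab[valid] / a0[valid]) / b
    return adc


def brain_mask(mag, threshold_fraction: float = 0.1) -> np.ndarray:
    """Threshold mask: voxels above ``threshold_fraction * max``, reduced to
    the largest 3D connected component, with interior holes filled."""
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    arr = _arr(mag)
    bw = arr > threshold_fraction * arr.max()
    if not bw.any():
        raise ValueError("empty mask: no voxel exceeds the threshold")
    lab, n = ndimage.label(bw)
    if n > 1:
        sizes = ndimage.sum_labels(bw, lab, index=np.arange(1, n + 1))
        bw = lab == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(bw)


def evaluate_pair(ref, test, mask=None, data_range=None) -> MetricReport:
    """PSNR/SSIM/MSE bundle for one reconstruction against its reference."""
    r = _arr(ref)
    n = int(np.asarray(mask, bool).sum()) if mask is not None else int(r.size)
    return MetricReport(
        psnr=psnr(ref, test, data_range=data_range, mask=mask),
        ssim=ssim(ref, test, data_range=data_range, mask=mask),
        mse=mse(ref, test, mask=mask),
        n_voxels=n,
        mask_description="brain mask" if mask is not None else "whole image",
    )
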