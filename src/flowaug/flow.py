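"""Displacement and intensity flow fields and the operators that apply them.

A displacement flow is a voxel-wise mapping ``phi(x) = x + u(x)`` with ``u``
in voxel units; volumes are warped by *backward* (pull) sampling, i.e. the
output value at voxel ``x`` is the input interpolated at ``x + u(x)``.  An
intensity flow ``psi`` is an additive per-voxel delta applied to magnitude
volumes, optionally scaled by a factor ``m``.

Axis convention throughout the package: arrays are ``(z, y, x)`` with
0-based indices; vector fields are ``(3, z, y, x)`` with components ordered
``(dz, dy, dx)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np
from scipy import ndimage

__all__ = [
    "DisplacementField",
    "IntensityField",
    "MagnitudeVolume",
    "FlowInversionError",
    "identity_field",
    "warp_scalar",
    "warp_phase",
    "apply_intensity",
    "compose_fields",
    "invert_field",
]


class FlowInversionError(RuntimeError):
    """Fixed-point field inversion failed to converge; carries the residual."""

    def __init__(self, residual: float, iterations: int):
        self.residual = float(residual)
        self.iterations = int(iterations)
        super().__init__(
            f"field inversion did not reach tolerance after {iterations} "
            f"iterations (residual {residual:.3g} voxels)"
        )


@dataclass
class DisplacementField:
    """Voxel-wise offsets ``u`` defining the flow ``phi = I + u``.

    Parameters
    ----------
    u : ndarray, shape (3, nz, ny, nx)
        Offsets in voxel units, components ordered (dz, dy, dx).
    interpolation : {"linear", "nearest"}
        Interpolation used when this field warps a volume.
    boundary : {"clamp", "zero"}
        Out-of-bounds rule: clamp to the border value or fill with zero.
    """

    u: np.ndarray
    interpolation: str = "linear"
    boundary: str = "clamp"

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 4 or self.u.shape[0] != 3:
            raise ValueError(f"u must have shape (3, nz, ny, nx), got {self.u.shape}")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field contains non-finite values")
        if self.interpolation not in ("linear", "nearest"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        if self.boundary not in ("clamp", "zero"):
            raise ValueError(f"unknown boundary {self.boundary!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.u.shape[1:]

    def max_norm(self) -> float:
        """Largest per-voxel endpoint length ``max_x |u(x)|`` (voxels)."""
        return float(np.sqrt((self.u ** 2).sum(axis=0)).max())


@dataclass
class IntensityField:
    """Additive per-voxel intensity deltas ``psi``, applied as ``vol + m*psi``."""

    psi: np.ndarray
    scale: float = 1.0

    def __post_init__(self):
        self.psi = np.asarray(self.psi, dtype=np.float64)
        if self.psi.ndim != 3:
            raise ValueError(f"psi must be a 3D grid, got shape {self.psi.shape}")
        if not np.all(np.isfinite(self.psi)):
            raise ValueError("intensity field contains non-finite values")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.psi.shape


@dataclass
class MagnitudeVolume:
    """Non-negative scalar volume on a regular (z, y, x) grid."""

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        if self.values.min() < 0:
            raise ValueError("magnitude volumes must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def _as_array(vol) -> np.ndarray:
    if isinstance(vol, MagnitudeVolume):
        return vol.values
    return np.asarray(vol)


def identity_field(shape, **kwargs) -> DisplacementField:
    """The zero-displacement field (``phi = I``) on ``shape``."""
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValueError(f"invalid shape {shape}")
    return DisplacementField(np.zeros((3, *shape)), **kwargs)


def _sample_coords(field: DisplacementField) -> np.ndarray:
    base = np.indices(field.shape, dtype=np.float64)
    return base + field.u


def warp_scalar(vol, field: DisplacementField) -> np.ndarray:
    """Pull-warp a scalar grid: ``out(x) = vol(x + u(x))``."""
    arr = _as_array(vol)
    if arr.shape != field.shape:
        raise ValueError(f"volume shape {arr.shape} != field shape {field.shape}")
    if not field.u.any():  # zero field: exact identity, no interpolation error
        return arr.astype(np.float64, copy=True)
    order = 1 if field.interpolation == "linear" else 0
    mode = "nearest" if field.boundary == "clamp" else "constant"
    return ndimage.map_coordinates(
        arr.astype(np.float64), _sample_coords(field), order=order, mode=mode, cval=0.0
    )


def warp_phase(phase, field: DisplacementField) -> np.ndarray:
    """Warp a phase grid (radians) via its cos/sin channels.

    Interpolating a wrapped angle directly produces spurious values at the
    +/-pi seam; interpolating cos and sin and re-extracting the angle does
    not.  The result lies in (-pi, pi].
    """
    arr = _as_array(phase)
    if arr.shape != field.shape:
        raise ValueError(f"phase shape {arr.shape} != field shape {field.shape}")
    c = warp_scalar(np.cos(arr), field)
    s = warp_scalar(np.sin(arr), field)
    out = np.arctan2(s, c)
    out[out == -np.pi] = np.pi
    return out


def apply_intensity(vol, psi, m: float = 1.0):
    """Apply an intensity flow: ``max(vol + m*psi, 0)``.

    Magnitude data stay non-negative, so the sum is clipped at zero.
    Returns the same container type as ``vol``.
    """
    arr = _as_array(vol)
    p = psi.psi if isinstance(psi, IntensityField) else np.asarray(psi)
    if arr.shape != p.shape:
        raise ValueError(f"volume shape {arr.shape} != psi shape {p.shape}")
    if m <= 0:
        raise ValueError("intensity scale m must be positive")
    out = np.clip(arr + m * p, 0.0, None)
    if isinstance(vol, MagnitudeVolume):
        return MagnitudeVolume(out, vol.voxel_size)
    return out


def compose_fields(f_outer: DisplacementField, f_inner: DisplacementField) -> DisplacementField:
    """Field whose warp equals warping by ``f_inner`` then ``f_outer``.

    In pull-warp terms ``u(x) = u_outer(x) + u_inner(x + u_outer(x))``.
    """
    if f_outer.shape != f_inner.shape:
        raise ValueError("field shapes differ")
    u = np.stack([warp_scalar(f_inner.u[d], f_outer) for d in range(3)])
    return DisplacementField(
        f_outer.u + u, interpolation=f_outer.interpolation, boundary=f_outer.boundary
    )


def _max_axis_gradient(u: np.ndarray) -> float:
    """max over axes d of max |d u_d / d x_d| — folding indicator."""
    g = 0.0
    for d in range(3):
        if u.shape[1 + d] > 1:
            g = max(g, float(np.abs(np.diff(u[d], axis=d)).max()))
    return g


def invert_field(
    field: DisplacementField, iterations: int = 50, tol: float = 1e-2
) -> DisplacementField:
    """Numerically invert a non-folding displacement field.

    Uses the fixed-point iteration ``v_{k+1}(x) = -u(x + v_k(x))``; at the
    fixed point, warping by ``field`` and then by the inverse is the
    identity.  Raises :class:`FlowInversionError` when the update residual
    does not drop below ``tol`` (voxels) on the interior.
    """
    if _max_axis_gradient(field.u) >= 1.0:
        raise ValueError("field appears to fold (max per-axis |grad u| >= 1); cannot invert")
    v = np.zeros_like(field.u)
    interior = tuple(
        slice(1, -1) if s > 2 else slice(None) for s in field.shape
    )
    residual = np.inf
    for _ in range(iterations):
        vf = DisplacementField(v, field.interpolation, field.boundary)
        v_new = -np.stack([warp_scalar(field.u[d], vf) for d in range(3)])
        residual = float(np.abs((v_new - v)[(slice(None), *interior)]).max())
        v = v_new
        if residual <= tol:
            return DisplacementField(v, field.interpolation, field.boundary)
    raise FlowInversionError(residual, iterations)
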