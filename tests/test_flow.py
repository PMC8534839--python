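"""Displacement/intensity field operators: warping, composition, inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flowaug.flow import (
    DisplacementField,
    FlowInversionError,
    IntensityField,
    MagnitudeVolume,
    apply_intensity,
    compose_fields,
    identity_field,
    invert_field,
    warp_phase,
    warp_scalar,
)

SHAPE = (6, 10, 12)


def smooth_field(shape, amplitude, seed, sigma=3.0):
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    u = np.stack([ndimage.gaussian_filter(rng.standard_normal(shape), sigma) for _ in range(3)])
    u *= amplitude / max(np.abs(u).max(), 1e-12)
    return DisplacementField(u)


def smooth_volume(shape, seed):
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    return ndimage.gaussian_filter(rng.standard_normal(shape), 2.0)


class TestWarpScalar:
    def test_identity_is_exact(self):
        rng = np.random.default_rng(0)
        vol = rng.random(SHAPE)
        for interp in ("linear", "nearest"):
            out = warp_scalar(vol, identity_field(SHAPE, interpolation=interp))
            np.testing.assert_array_equal(out, vol)

    def test_constant_translation_moves_impulse(self):
        # pull-warp: out(x) = vol(x + u), so u = (0,0,+3) moves the impulse
        # from (4,4,4) to (4,4,1)
        vol = np.zeros((8, 8, 8))
        vol[4, 4, 4] = 1.0
        u = np.zeros((3, 8, 8, 8))
        u[2] = 3.0
        out = warp_scalar(vol, DisplacementField(u, interpolation="nearest", boundary="zero"))
        expected = np.zeros_like(vol)
        expected[4, 4, 1] = 1.0
        np.testing.assert_array_equal(out, expected)

    def test_matches_brute_force_loop(self):
        """Vectorized pull-warp equals explicit per-voxel index arithmetic."""
        rng = np.random.default_rng(1)
        vol = rng.random((5, 6, 7))
        u = rng.integers(-2, 3, size=(3, 5, 6, 7)).astype(float)
        out = warp_scalar(vol, DisplacementField(u, interpolation="nearest", boundary="zero"))
        expected = np.zeros_like(vol)
        for z in range(5):
            for y in range(6):
                for x in range(7):
                    zz, yy, xx = (
                        z + int(u[0, z, y, x]),
                        y + int(u[1, z, y, x]),
                        x + int(u[2, z, y, x]),
                    )
                    if 0 <= zz < 5 and 0 <= yy < 6 and 0 <= xx < 7:
                        expected[z, y, x] = vol[zz, yy, xx]
        np.testing.assert_allclose(out, expected)

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 1000), amp=st.floats(0.1, 2.0))
    def test_constant_volume_invariant(self, seed, amp):
        """Interpolating a constant volume returns that constant."""
        field = smooth_field(SHAPE, amp, seed)
        out = warp_scalar(np.full(SHAPE, 3.25), field)
        np.testing.assert_allclose(out, 3.25, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            warp_scalar(np.zeros((4, 4, 4)), identity_field(SHAPE))


class TestWarpPhase:
    def test_agrees_with_scalar_warp_when_no_wrap(self):
        # gentle phase: away from the wrap, cos/sin-channel warping and
        # direct angle interpolation agree to third order in the phase step
        phase = np.clip(0.05 * smooth_volume(SHAPE, 2), -1.4, 1.4)
        field = smooth_field(SHAPE, 1.0, 3)
        np.testing.assert_allclose(
            warp_phase(phase, field), warp_scalar(phase, field), atol=1e-6
        )

    def test_constant_phase_preserved(self):
        field = smooth_field(SHAPE, 1.5, 4)
        out = warp_phase(np.full(SHAPE, 2.9), field)
        np.testing.assert_allclose(out, 2.9, atol=1e-10)

    def test_wrapping_ramp_has_no_seam_artifacts(self):
        """A ramp crossing +/-pi, shifted by a small translation, must match
        the shift of the unwrapped ramp re-wrapped — no values collapsing
        toward 0 at the seam, as naive interpolation of the angle would give.
        """
        shape = (4, 8, 64)
        x = np.arange(shape[2])
        ramp = np.angle(np.exp(1j * (0.2 * x - np.pi)))  # wraps several times
        phase = np.broadcast_to(ramp, shape).copy()
        u = np.zeros((3, *shape))
        u[2] = 0.5
        out = warp_phase(phase, DisplacementField(u))
        unwrapped = np.broadcast_to(0.2 * (x + 0.5) - np.pi, shape)
        expected = np.arctan2(np.sin(unwrapped), np.cos(unwrapped))
        interior = (slice(None), slice(None), slice(1, -2))
        err = np.angle(np.exp(1j * (out - expected)))[interior]
        assert np.abs(err).max() < 0.02

    def test_output_range(self):
        field = smooth_field(SHAPE, 1.0, 5)
        out = warp_phase(np.pi * smooth_volume(SHAPE, 6), field)
        assert out.min() > -np.pi and out.max() <= np.pi


class TestApplyIntensity:
    def test_zero_psi_is_identity(self):
        vol = np.abs(smooth_volume(SHAPE, 7))
        np.testing.assert_array_equal(apply_intensity(vol, np.zeros(SHAPE)), vol)

    def test_constant_offset(self):
        vol = np.abs(smooth_volume(SHAPE, 8)) + 1.0
        out = apply_intensity(vol, np.full(SHAPE, 0.3))
        np.testing.assert_allclose(out, vol + 0.3)

    def test_scaled_delta_where_unclipped(self):
        rng = np.random.default_rng(9)
        vol = rng.random(SHAPE) + 0.5
        psi = rng.normal(0, 0.2, SHAPE)
        out = apply_intensity(vol, psi, m=1.2)
        unclipped = vol + 1.2 * psi >= 0
        np.testing.assert_allclose((out - vol)[unclipped], 1.2 * psi[unclipped])
        assert out.min() >= 0

    def test_magnitude_volume_roundtrip(self):
        mv = MagnitudeVolume(np.abs(smooth_volume(SHAPE, 10)))
        out = apply_intensity(mv, IntensityField(np.zeros(SHAPE)), m=2.0)
        assert isinstance(out, MagnitudeVolume)


class TestComposeInvert:
    def test_compose_with_identity(self):
        f = smooth_field(SHAPE, 1.0, 11)
        comp = compose_fields(f, identity_field(SHAPE))
        np.testing.assert_allclose(comp.u, f.u, atol=1e-10)
        comp2 = compose_fields(identity_field(SHAPE), f)
        np.testing.assert_allclose(comp2.u, f.u, atol=1e-10)

    def test_constant_translations_add(self):
        u1 = np.zeros((3, *SHAPE))
        u1[1] = 1.0
        u2 = np.zeros((3, *SHAPE))
        u2[2] = -2.0
        comp = compose_fields(DisplacementField(u1), DisplacementField(u2))
        np.testing.assert_allclose(comp.u[1], 1.0)
        np.testing.assert_allclose(comp.u[2], -2.0)

    def test_compose_matches_two_step_warp(self):
        vol = smooth_volume(SHAPE, 12)
        f_in = smooth_field(SHAPE, 0.8, 13)
        f_out = smooth_field(SHAPE, 0.8, 14)
        two_step = warp_scalar(warp_scalar(vol, f_in), f_out)
        one_step = warp_scalar(vol, compose_fields(f_out, f_in))
        interior = tuple(slice(1, -1) for _ in SHAPE)
        err = np.abs(two_step - one_step)[interior].max()
        assert err < 0.05 * (vol.max() - vol.min())

    def test_invert_constant_translation(self):
        u = np.zeros((3, *SHAPE))
        u[2] = 1.5
        inv = invert_field(DisplacementField(u), tol=1e-6)
        np.testing.assert_allclose(inv.u[2], -1.5, atol=1e-6)
        np.testing.assert_allclose(inv.u[[0, 1]], 0.0, atol=1e-6)

    def test_invert_identity(self):
        inv = invert_field(identity_field(SHAPE), tol=1e-9)
        np.testing.assert_allclose(inv.u, 0.0)

    def test_roundtrip_warp_smooth_field(self):
        shape = (8, 24, 24)
        vol = smooth_volume(shape, 15)
        f = smooth_field(shape, 1.0, 16, sigma=4.0)
        inv = invert_field(f, iterations=80, tol=1e-4)
        back = warp_scalar(warp_scalar(vol, f), inv)
        interior = tuple(slice(3, -3) for _ in shape)
        err = np.abs(back - vol)[interior].max()
        assert err < 0.02 * (vol.max() - vol.min())

    def test_compose_of_field_and_inverse_is_small(self):
        f = smooth_field(SHAPE, 0.8, 17)
        inv = invert_field(f, iterations=80, tol=1e-5)
        comp = compose_fields(inv, f)
        interior = (slice(None), *[slice(2, -2) for _ in SHAPE])
        assert np.abs(comp.u[interior]).max() < 1e-3

    def test_folding_field_rejected(self):
        u = np.zeros((3, *SHAPE))
        u[2] = np.tile(np.arange(SHAPE[2]) % 2 * 3.0, (SHAPE[0], SHAPE[1], 1))
        with pytest.raises(ValueError, match="fold"):
            invert_field(DisplacementField(u))

    def test_nonconvergence_raises_with_residual(self):
        f = smooth_field(SHAPE, 0.9, 18)
        with pytest.raises(FlowInversionError) as exc:
            invert_field(f, iterations=1, tol=1e-12)
        assert exc.value.residual > 0


def test_identity_field_validates_shape():
    with pytest.raises(ValueError):
        identity_field((0, 4, 4))


def test_non_finite_field_rejected():
    u = np.zeros((3, *SHAPE))
    u[0, 0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        DisplacementField(u)
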