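"""Complex augmentation: magnitude/phase handling, flow application to
DWI and coil maps, basic transforms, plan enumeration and streaming."""

import h5py
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flowaug as fa
from flowaug.augment import (
    AugmentationPlan,
    CoilSensitivityMaps,
    M_LIST_ALT,
    augment_csm,
    augment_dwi,
    basic_transform,
    basic_transform_complex,
    enumerate_plan,
    merge_mag_phase,
    run_plan,
    split_mag_phase,
)
from flowaug.flow import DisplacementField, identity_field


def smooth_field(shape, amplitude, seed, sigma=3.0):
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    u = np.stack([ndimage.gaussian_filter(rng.standard_normal(shape), sigma) for _ in range(3)])
    u *= amplitude / max(np.abs(u).max(), 1e-12)
    return DisplacementField(u)


class TestMagPhase:
    def test_pythagorean_point(self):
        mag, ph = split_mag_phase(np.full((1, 1, 1), 3 + 4j))
        assert mag[0, 0, 0] == pytest.approx(5.0)
        assert ph[0, 0, 0] == pytest.approx(np.arctan2(4, 3))

    def test_negative_real_axis_gives_pi(self):
        _, ph = split_mag_phase(np.full((1, 1, 1), -1 + 0j))
        assert ph[0, 0, 0] == pytest.approx(np.pi)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_merge_split_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.standard_normal((3, 4, 5)) + 1j * rng.standard_normal((3, 4, 5))
        mag, ph = split_mag_phase(v)
        back = merge_mag_phase(mag, ph)
        np.testing.assert_allclose(back, v, rtol=1e-6, atol=1e-12)
        assert ph.min() > -np.pi and ph.max() <= np.pi

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            merge_mag_phase(np.full((2, 2, 2), -1.0), np.zeros((2, 2, 2)))

    def test_zero_magnitude_any_phase_is_zero(self):
        out = merge_mag_phase(np.zeros((2, 2, 2)), np.full((2, 2, 2), 2.2))
        np.testing.assert_array_equal(out, 0)


@pytest.fixture(scope="module")
def dwi_and_csm():
    spec = fa.PhantomSpec(grid_shape=(8, 24, 24), n_coils=4, noise_sigma=0.0, seed=12)
    vol, labels = fa.make_brain_phantom(spec)
    csm = fa.make_coil_maps(spec)
    case = fa.make_dwi_case(spec, vol, labels, csm)
    return case, csm, labels


class TestAugmentCSM:
    def test_identity_field_preserves_maps(self, dwi_and_csm):
        _, csm, _ = dwi_and_csm
        out = augment_csm(csm, identity_field(csm.shape))
        np.testing.assert_allclose(out.maps, csm.maps, atol=1e-12)

    def test_translation_commutes_with_rss(self, dwi_and_csm):
        _, csm, _ = dwi_and_csm
        u = np.zeros((3, *csm.shape))
        u[1], u[2] = 1.0, -1.5
        f = DisplacementField(u)
        out = augment_csm(csm, f)
        from flowaug.flow import warp_scalar

        rss_then_warp = warp_scalar(csm.rss(), f)
        interior = tuple(slice(2, -2) for _ in csm.shape)
        assert np.abs(out.rss()[interior] - rss_then_warp[interior]).max() < 0.05

    def test_intensity_preservation(self, dwi_and_csm):
        """Displacement-only warping leaves the coil magnitude statistics
        essentially unchanged (no intensity flow ever touches the CSM)."""
        _, csm, _ = dwi_and_csm
        f = smooth_field(csm.shape, 1.0, 5)
        out = augment_csm(csm, f)
        assert np.abs(out.maps).min() >= 0
        change = abs(np.abs(out.maps).mean() / np.abs(csm.maps).mean() - 1)
        assert change < 0.02


class TestAugmentDWI:
    def test_identity_noop(self, dwi_and_csm):
        case, _, _ = dwi_and_csm
        out = augment_dwi(case.dwi, identity_field(case.dwi.shape), np.zeros(case.dwi.shape))
        np.testing.assert_allclose(out, case.dwi, atol=1e-12)

    def test_zero_psi_magnitude_equals_warped_magnitude(self, dwi_and_csm):
        case, _, _ = dwi_and_csm
        f = smooth_field(case.dwi.shape, 1.0, 6)
        out = augment_dwi(case.dwi, f, np.zeros(case.dwi.shape))
        from flowaug.flow import warp_scalar

        np.testing.assert_allclose(np.abs(out), warp_scalar(np.abs(case.dwi), f), atol=1e-9)

    def test_constant_psi_identity_field(self, dwi_and_csm):
        case, _, labels = dwi_and_csm
        c = 0.01
        out = augment_dwi(case.dwi, identity_field(case.dwi.shape), np.full(case.dwi.shape, c), m=1.1)
        np.testing.assert_allclose(np.abs(out), np.abs(case.dwi) + 1.1 * c, atol=1e-12)

    def test_phase_independent_of_psi_and_m(self, dwi_and_csm):
        """Varying the intensity flow scale m must not move the phase."""
        case, _, _ = dwi_and_csm
        f = smooth_field(case.dwi.shape, 1.0, 7)
        rng = np.random.default_rng(0)
        psi = np.abs(rng.normal(0, 0.02, case.dwi.shape))
        outs = [augment_dwi(case.dwi, f, psi, m=m) for m in (0.8, 1.2)]
        nz = (np.abs(outs[0]) > 1e-9) & (np.abs(outs[1]) > 1e-9)
        dphi = np.angle(outs[0] * np.conj(outs[1]))[nz]
        assert np.abs(dphi).max() < 1e-9

    def test_heavy_clipping_warns(self, dwi_and_csm):
        case, _, _ = dwi_and_csm
        psi = np.full(case.dwi.shape, -10.0)
        with pytest.warns(RuntimeWarning, match="negative"):
            augment_dwi(case.dwi, identity_field(case.dwi.shape), psi)


class TestBasicTransforms:
    def test_zero_rotation_identity(self, dwi_and_csm):
        case, _, _ = dwi_and_csm
        mag = np.abs(case.b0)
        np.testing.assert_allclose(basic_transform(mag, "rotate", 0.0), mag, atol=1e-12)

    def test_brightness_one_identity(self, dwi_and_csm):
        case, _, _ = dwi_and_csm
        mag = np.abs(case.b0)
        np.testing.assert_array_equal(basic_transform(mag, "brightness", 1.0), mag)

    def test_translation_inverse_pair(self, dwi_and_csm):
        case, _, _ = dwi_and_csm
        mag = np.abs(case.b0)
        fwd = basic_transform(mag, "translate", (6.0, 0.0))
        back = basic_transform(fwd, "translate", (-6.0, 0.0))
        interior = (slice(None), slice(2, -2), slice(8, -8))
        assert np.abs(back - mag)[interior].max() < 0.02 * mag.max()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            basic_transform(np.zeros((2, 4, 4)), "swirl", 1.0)

    def test_complex_brightness_scales_magnitude_only(self, dwi_and_csm):
        case, _, _ = dwi_and_csm
        out = basic_transform_complex(case.dwi, "brightness", 0.8)
        np.testing.assert_allclose(np.abs(out), 0.8 * np.abs(case.dwi), atol=1e-12)
        nz = np.abs(case.dwi) > 1e-9
        np.testing.assert_allclose(np.angle(out)[nz], np.angle(case.dwi)[nz], atol=1e-9)


class TestPlans:
    @pytest.mark.parametrize(
        "group,expected",
        [("s", 20), ("r", 40), ("t", 80), ("srt", 2560), ("d", 2080), ("di", 2704)],
    )
    def test_group_counts(self, group, expected):
        plan = AugmentationPlan(group=group)
        assert plan.count() == expected
        assert sum(1 for _ in enumerate_plan(plan)) == expected

    def test_di_with_displacement_only_variant(self):
        plan = AugmentationPlan(group="di", include_displacement_only=True)
        assert plan.count() == 2730

    def test_alt_m_list_profile(self):
        plan = AugmentationPlan(group="di", m_list=M_LIST_ALT)
        assert plan.count() == 26 * 26 * 4

    def test_enumeration_is_deterministic(self):
        plan = AugmentationPlan(group="s")
        assert list(enumerate_plan(plan)) == list(enumerate_plan(plan))

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            AugmentationPlan(group="x")

    def test_empty_required_list_rejected(self):
        plan = AugmentationPlan(group="s", brightness_list=())
        with pytest.raises(ValueError, match="non-empty"):
            list(enumerate_plan(plan))


class TestRunPlan:
    def test_group_s_streams_twenty_cases(self, small_phantom_case, tmp_path):
        pc = small_phantom_case
        src = {"dwi_b0": pc["case"].b0, "dwi_b1000": pc["case"].dwi, "csm": pc["csm"]}
        out = tmp_path / "aug_s.h5"
        n = run_plan(AugmentationPlan(group="s"), src, [], out)
        assert n == 20
        with h5py.File(out) as f:
            assert len(f.keys()) == 20
            for name in f:
                grp = f[name]
                for ds in ("dwi_b0", "dwi_b1000", "csm"):
                    arr = grp[ds][()]
                    assert np.isfinite(arr).all()
                assert grp["csm"].shape[0] == pc["csm"].n_coils
                assert "descriptor" in grp.attrs

    def test_flow_group_with_empty_flows_errors(self, small_phantom_case, tmp_path):
        pc = small_phantom_case
        src = {"dwi_b0": pc["case"].b0, "dwi_b1000": pc["case"].dwi, "csm": pc["csm"]}
        with pytest.raises(ValueError, match="needs flows"):
            run_plan(AugmentationPlan(group="d", n_geometry_targets=2), src, [],
                     tmp_path / "aug_d.h5")

    def test_flow_group_counts_with_flows(self, small_phantom_case, tmp_path):
        pc = small_phantom_case
        shape = pc["case"].b0.shape
        flows = [
            (smooth_field(shape, 0.5, i), 0.01 * np.ones(shape)) for i in range(2)
        ]
        src = {"dwi_b0": pc["case"].b0, "dwi_b1000": pc["case"].dwi, "csm": pc["csm"]}
        plan = AugmentationPlan(
            group="di", n_geometry_targets=2, n_intensity_targets=2, m_list=(0.9, 1.1)
        )
        n = run_plan(plan, src, flows, tmp_path / "aug_di.h5")
        assert n == plan.count() == 2 * 2 * 2
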