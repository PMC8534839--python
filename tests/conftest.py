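"""Shared fixtures: phantoms and (expensive) trained flow models.

Trained-model fixtures are session-scoped so each network is fitted once
and reused by every test that inspects it.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

import flowaug as fa
from flowaug.flow import DisplacementField, MagnitudeVolume, warp_scalar
from flowaug.learn import (
    FlowNetConfig,
    train_displacement_net,
    train_intensity_net,
    train_inverse_displacement_net,
)


@pytest.fixture(scope="session")
def phantom_case():
    """Anatomy, coil maps and a noiseless DWI case on a 16x64x64 grid."""
    spec = fa.PhantomSpec(grid_shape=(16, 64, 64), n_coils=8, noise_sigma=0.0, seed=3)
    vol, labels = fa.make_brain_phantom(spec)
    csm = fa.make_coil_maps(spec)
    case = fa.make_dwi_case(spec, vol, labels, csm)
    return {"spec": spec, "vol": vol, "labels": labels, "csm": csm, "case": case}


@pytest.fixture(scope="session")
def small_phantom_case():
    """Small, fast variant for I/O and augmentation streaming tests."""
    spec = fa.PhantomSpec(grid_shape=(8, 16, 16), n_coils=2, seed=0)
    vol, labels = fa.make_brain_phantom(spec)
    csm = fa.make_coil_maps(spec)
    case = fa.make_dwi_case(spec, vol, labels, csm)
    return {"spec": spec, "vol": vol, "labels": labels, "csm": csm, "case": case}


def interior_mask(labels: np.ndarray, iterations: int = 3) -> np.ndarray:
    """In-plane erosion of the anatomy support: the region where a flow is
    identifiable and free of boundary interpolation mixing."""
    return ndimage.binary_erosion(
        labels > 0, structure=np.ones((1, 3, 3), bool), iterations=iterations
    )


@pytest.fixture(scope="session")
def translation_models():
    """Forward + inverse displacement nets trained on a known 2-voxel
    in-plane translation of a textured phantom (smoothness-regularized)."""
    spec = fa.PhantomSpec(grid_shape=(8, 24, 24), seed=5)
    vol, labels = fa.make_brain_phantom(spec)
    u_true = np.zeros((3, *vol.shape))
    u_true[2] = 2.0  # +2 voxels along x
    phi_true = DisplacementField(u_true)
    target = MagnitudeVolume(np.clip(warp_scalar(vol, phi_true), 0.0, None))
    cfg = FlowNetConfig(
        iterations=500, learning_rate=2e-3, batch_size=1, seed=0, smoothness_weight=0.2
    )
    fwd = train_displacement_net([(vol, target)], cfg)
    inv = train_inverse_displacement_net([(vol, target)], cfg)
    return {
        "source": vol,
        "target": target,
        "labels": labels,
        "u_true": u_true,
        "phi_true": phi_true,
        "forward": fwd,
        "inverse": inv,
        "config": cfg,
    }


@pytest.fixture(scope="session")
def offset_models():
    """Inverse + intensity nets trained on a pair differing only by a
    constant intensity offset inside a single-tissue phantom."""
    spec = fa.PhantomSpec(grid_shape=(8, 24, 24), n_tissues=1, seed=2)
    vol, labels = fa.make_brain_phantom(spec)
    offset = 0.15
    target = MagnitudeVolume(np.clip(vol.values + offset * (labels > 0), 0.0, None))
    # the true inverse here is the zero field, so the inverse net is
    # smoothness-regularized; the intensity net is not (psi is a sharp step)
    cfg = FlowNetConfig(
        iterations=400, learning_rate=2e-3, batch_size=1, seed=0, smoothness_weight=0.2
    )
    cfg_int = FlowNetConfig(iterations=400, learning_rate=2e-3, batch_size=1, seed=0)
    inv = train_inverse_displacement_net([(vol, target)], cfg)
    intensity = train_intensity_net([(vol, target)], inv, cfg_int)
    return {
        "source": vol,
        "target": target,
        "labels": labels,
        "offset": offset,
        "inverse": inv,
        "intensity": intensity,
        "config": cfg,
    }


@pytest.fixture(scope="session")
def smooth_pair_model():
    """Forward displacement net trained on a smooth random 2-voxel field."""
    spec = fa.PhantomSpec(
        grid_shape=(8, 24, 24), deform_amplitude=2.0, deform_smoothness=5.0,
        intensity_amplitude=0.0, seed=1,
    )
    bundle = fa.make_subject_pair(spec, seed=101)
    cfg = FlowNetConfig(iterations=500, learning_rate=2e-3, batch_size=1, seed=0)
    model = train_displacement_net([(bundle.source, bundle.target)], cfg)
    return {"bundle": bundle, "model": model, "config": cfg}


@pytest.fixture(scope="session")
def tiny_pipeline_runs(tmp_path_factory):
    """Two identically-seeded runs of the miniature end-to-end pipeline."""
    from flowaug.learn import FlowNetConfig
    from flowaug.pipeline import PipelineConfig, run_pipeline

    cfg = PipelineConfig(
        seed=11,
        phantom=fa.PhantomSpec(grid_shape=(8, 24, 24), n_coils=3),
        flow=FlowNetConfig(iterations=60, batch_size=2),
        n_targets=2,
        groups=("s",),
        R_values=(4,),
        patterns=("uniform",),
    )
    root = tmp_path_factory.mktemp("pipeline")
    df1 = run_pipeline(cfg, out_root=root / "run1")
    df2 = run_pipeline(cfg, out_root=root / "run2")
    return {
        "config": cfg,
        "df1": df1,
        "df2": df2,
        "csv1": (root / "run1" / "metrics.csv").read_bytes(),
        "csv2": (root / "run2" / "metrics.csv").read_bytes(),
        "root": root,
    }
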