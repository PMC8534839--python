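"""Training of the displacement, inverse-displacement and intensity flow
regressors on anatomical volume pairs.

Three 3D U-Nets are fitted by Adam on pure mean-squared-error objectives:

* forward displacement:  ``L_d = || T - S o phi ||^2`` with ``phi = I + u``
  predicted from the channel-concatenated pair (S, T);
* inverse displacement: the same objective with source and target roles
  swapped, yielding the field ``phi_inv`` that pulls the target back to the
  source geometry;
* intensity: with the target pulled back through ``phi_inv``, the network
  regresses the additive residual, ``L_i = || T o phi_inv - (S + psi) ||^2``.

Each pair is min-max normalized on the source volume's scale before
training (so the source spans [0, 1] and genuine contrast differences in
the target survive); the intensity field is learned in those normalized
units and rescaled to source intensity units on prediction.  An optional
diffusion (smoothness) penalty on the predicted field is available via
``smoothness_weight`` and off by default.  Training is fully
deterministic for a fixed config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .flow import DisplacementField, IntensityField, MagnitudeVolume, invert_field, warp_scalar
from .nn import Adam, Tensor, UNet3D, add_scaled, grad_penalty, mse_loss, warp_volume

__all__ = [
    "FlowNetConfig",
    "FlowModel",
    "PRODUCTION_SCALE_CONFIG",
    "train_displacement_net",
    "train_inverse_displacement_net",
    "train_intensity_net",
    "predict_flows",
]


@dataclass(frozen=True)
class FlowNetConfig:
    """Hyperparameters of one flow-regression network.

    Defaults are the desk-scale profile used throughout the test-bench
    (small grids, few hundred iterations); ``PRODUCTION_SCALE_CONFIG`` carries
    the production-scale settings (batch 40, 10^4 iterations).
    """

    unet_levels: int = 2
    base_channels: int = 8
    learning_rate: float = 1e-3
    batch_size: int = 4
    iterations: int = 500
    seed: int = 0
    device: str = "cpu"
    smoothness_weight: float = 0.0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.device not in ("cpu", "accelerator"):
            raise ValueError("device must be 'cpu' or 'accelerator'")


#: Production-scale profile (large-batch Adam at 1e-3 over 10^4 iterations).
PRODUCTION_SCALE_CONFIG = FlowNetConfig(batch_size=40, iterations=10_000)


def _raw(vol) -> np.ndarray:
    return vol.values if isinstance(vol, MagnitudeVolume) else np.asarray(vol, float)


def _pair_norm(source, target) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Normalize a pair on the *source's* min-max scale.

    Both volumes share the source's affine scaling, so relative intensity
    differences between target and source — exactly what the intensity
    network must regress — survive normalization.
    """
    s, t = _raw(source), _raw(target)
    lo, hi = float(s.min()), float(s.max())
    rng = hi - lo
    if rng <= 0:
        lo, rng = 0.0, 1.0
    return (s - lo) / rng, (t - lo) / rng, lo, rng


def _check_pairs(pairs):
    norm = [_pair_norm(s, t) for s, t in pairs]
    if not norm:
        raise ValueError("at least one (source, target) pair is required")
    shape = norm[0][0].shape
    for s, t, _, _ in norm:
        if s.shape != shape or t.shape != shape:
            raise ValueError("all pair volumes must share one grid shape")
    return [(s, t, rng) for s, t, _, rng in norm], shape


class FlowModel:
    """A trained flow regressor (displacement, inverse displacement or
    intensity role) with its config and loss history."""

    def __init__(self, role: str, net: UNet3D, config: FlowNetConfig, loss_history=None):
        if role not in ("displacement", "inverse_displacement", "intensity"):
            raise ValueError(f"unknown role {role!r}")
        self.role = role
        self.net = net
        self.config = config
        self.loss_history = list(loss_history or [])
        self.trained = bool(loss_history)

    def _forward(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        x = Tensor(np.stack([a, b])[None].astype(np.float32))
        return self.net(x).data[0].astype(np.float64)

    def predict(self, source, target):
        """Predict the flow for one (source, target) volume pair.

        Returns a :class:`DisplacementField` for displacement roles.  For
        the inverse role the returned field pulls the *target* back to the
        source geometry.  For the intensity role ``target`` must already be
        in source geometry (pulled back through the inverse flow); the
        result is an :class:`IntensityField` in source intensity units.
        """
        if not self.trained:
            raise RuntimeError("model has not been trained")
        s, t, _, s_rng = _pair_norm(source, target)
        if s.shape != t.shape:
            raise ValueError("source/target shapes differ")
        if self.role == "displacement":
            return DisplacementField(self._forward(s, t))
        if self.role == "inverse_displacement":
            return DisplacementField(self._forward(t, s))
        psi = self._forward(s, t)[0]
        return IntensityField(psi * s_rng)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        meta = {"role": self.role, "config": asdict(self.config),
                "loss_history": self.loss_history}
        arrays = {f"p{i}": a for i, a in enumerate(self.net.state_arrays())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path, in_channels=2) -> "FlowModel":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            arrays = [f[f"p{i}"] for i in range(len(f.files) - 1)]
        cfg = FlowNetConfig(**meta["config"])
        out_ch = 1 if meta["role"] == "intensity" else 3
        net = UNet3D(in_channels, out_ch, cfg.base_channels, cfg.unet_levels, cfg.seed)
        net.load_state_arrays(arrays)
        return cls(meta["role"], net, cfg, loss_history=meta["loss_history"] or [0.0])


def _train(
    inputs: list[tuple[np.ndarray, np.ndarray]],
    make_loss,
    out_channels: int,
    role: str,
    config: FlowNetConfig,
) -> FlowModel:
    shape = inputs[0][0].shape
    if config.unet_levels == 2 and any(s % 2 for s in shape):
        raise ValueError(f"grid dims must be even for a 2-level net, got {shape}")
    net = UNet3D(2, out_channels, config.base_channels, config.unet_levels, config.seed)
    opt = Adam(net.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    a_all = np.stack([a for a, _ in inputs]).astype(np.float32)
    b_all = np.stack([b for _, b in inputs]).astype(np.float32)
    n = len(inputs)
    bs = min(config.batch_size, n)
    history = []
    for it in range(config.iterations):
        idx = np.arange(n) if bs == n else rng.choice(n, size=bs, replace=False)
        x = Tensor(np.stack([a_all[idx], b_all[idx]], axis=1))
        pred = net(x)
        loss = make_loss(pred, idx)
        if config.smoothness_weight > 0:
            loss = add_scaled(loss, grad_penalty(pred), config.smoothness_weight)
        lval = float(loss.data)
        if not np.isfinite(lval):
            raise FloatingPointError(f"non-finite training loss at iteration {it}")
        history.append(lval)
        opt.zero_grad()
        loss.backward()
        opt.step()
    return FlowModel(role, net, config, loss_history=history)


def train_displacement_net(pairs, config: FlowNetConfig) -> FlowModel:
    """Fit the forward displacement regressor on (source, target) pairs.

    The loss is the MSE between the target and the source pull-warped by
    the predicted field, evaluated through a differentiable trilinear
    warp layer.
    """
    norm_pairs, _ = _check_pairs(pairs)
    srcs = np.stack([s for s, _, _ in norm_pairs]).astype(np.float32)
    tgts = np.stack([t for _, t, _ in norm_pairs]).astype(np.float32)

    def make_loss(pred, idx):
        warped = warp_volume(srcs[idx], pred)
        return mse_loss(warped, tgts[idx][:, None])

    return _train(
        [(s, t) for s, t, _ in norm_pairs], make_loss, 3, "displacement", config
    )


def train_inverse_displacement_net(pairs, config: FlowNetConfig) -> FlowModel:
    """Fit the inverse displacement regressor (target pulled back to source).

    Identical to :func:`train_displacement_net` with source and target
    roles swapped; the model's ``predict`` keeps the (source, target)
    calling convention and swaps internally.
    """
    model = train_displacement_net([(t, s) for s, t in pairs], config)
    return FlowModel("inverse_displacement", model.net, config, model.loss_history)


def train_intensity_net(pairs, inverse_model: FlowModel, config: FlowNetConfig) -> FlowModel:
    """Fit the intensity regressor on pulled-back pairs.

    For each pair the target is first mapped into source geometry through
    the trained inverse displacement; the network then regresses the
    voxel-wise additive residual so that ``source + psi`` matches the
    pulled-back target in the least-squares sense.
    """
    if inverse_model.role != "inverse_displacement":
        raise ValueError("inverse_model must have role 'inverse_displacement'")
    norm_pairs, _ = _check_pairs(pairs)
    inputs = []
    for (s_raw, t_raw), (s, t, _) in zip(pairs, norm_pairs):
        phi_inv = inverse_model.predict(s_raw, t_raw)
        tb = warp_scalar(t, phi_inv)
        inputs.append((s, tb))
    resid = np.stack([tb - s for s, tb in inputs]).astype(np.float32)

    def make_loss(pred, idx):
        return mse_loss(pred, resid[idx][:, None])

    return _train(inputs, make_loss, 1, "intensity", config)


def predict_flows(
    model_d: FlowModel,
    model_i: FlowModel,
    source,
    targets,
    inverse_model: FlowModel | None = None,
    invert_iterations: int = 30,
    invert_tol: float = 0.05,
):
    """Extract one (displacement, intensity) flow pair per target.

    The intensity network consumes the target pulled back to source
    geometry; the pull-back field comes from ``inverse_model`` when given,
    otherwise from numerical fixed-point inversion of the predicted
    forward field.  Output order matches ``targets``; prediction is
    deterministic for fixed weights.
    """
    out = []
    for t in targets:
        phi = model_d.predict(source, t)
        if inverse_model is not None:
            phi_inv = inverse_model.predict(source, t)
        else:
            phi_inv = invert_field(phi, iterations=invert_iterations, tol=invert_tol)
        t_arr = t.values if isinstance(t, MagnitudeVolume) else np.asarray(t, float)
        tb = warp_scalar(t_arr, phi_inv)
        psi = model_i.predict(source, tb)
        out.append((phi, psi))
    return out
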