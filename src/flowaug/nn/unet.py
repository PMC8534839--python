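"""A compact 3D U-Net for voxel-wise field regression.

Two volumes enter channel-concatenated; the output is a per-voxel field
(3 channels for displacement, 1 for intensity).  The head convolution is
zero-initialized so the network starts from the identity flow, which keeps
the warp layer's gradients well-behaved early in training.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, avg_pool2, concat, conv3d, leaky_relu, upsample2

__all__ = ["UNet3D"]


def _he_init(rng, cout, cin):
    fan_in = cin * 27
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, 3, 3, 3)).astype(
        np.float32
    )


class UNet3D:
    """3D U-Net with `levels` resolution levels (1 = plain conv stack)."""

    def __init__(self, in_channels: int, out_channels: int, base_channels: int = 8,
                 levels: int = 2, seed: int = 0):
        if levels not in (1, 2):
            raise ValueError("levels must be 1 or 2")
        rng = np.random.default_rng(seed)
        self.levels = levels
        c = base_channels
        self.params: list[Tensor] = []

        def conv_param(cout, cin, zero=False):
            w = Tensor(
                np.zeros((cout, cin, 3, 3, 3), np.float32) if zero else _he_init(rng, cout, cin),
                requires_grad=True,
            )
            b = Tensor(np.zeros(cout, np.float32), requires_grad=True)
            self.params += [w, b]
            return w, b

        self.enc1a = conv_param(c, in_channels)
        self.enc1b = conv_param(c, c)
        if levels == 2:
            self.bot_a = conv_param(2 * c, c)
            self.bot_b = conv_param(2 * c, 2 * c)
            self.dec1 = conv_param(c, 3 * c)
        self.head = conv_param(out_channels, c, zero=True)

    def __call__(self, x: Tensor) -> Tensor:
        h = leaky_relu(conv3d(x, *self.enc1a))
        h = leaky_relu(conv3d(h, *self.enc1b))
        if self.levels == 2:
            p = avg_pool2(h)
            p = leaky_relu(conv3d(p, *self.bot_a))
            p = leaky_relu(conv3d(p, *self.bot_b))
            h = leaky_relu(conv3d(concat(upsample2(p), h), *self.dec1))
        return conv3d(h, *self.head)

    # -- persistence -------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.params]

    def load_state_arrays(self, arrays) -> None:
        if len(arrays) != len(self.params):
            raise ValueError("state array count mismatch")
        for p, a in zip(self.params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.data = np.asarray(a, dtype=np.float32)
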