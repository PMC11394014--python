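"""Attention gate, squeeze-and-excitation and residual blocks.

The attention gate follows the additive formulation: the skip feature ``y``
and a gating signal ``omega`` (from the bridge/decoder side) are each mapped
by 1x1 convolutions, summed, passed through ReLU, reduced to a single
channel and squashed by a sigmoid; the resulting coefficients ``beta`` in
(0, 1) re-weight the skip feature pixel-wise.  When the two grids differ,
the gating signal is resampled to the skip grid by bilinear interpolation.

The SE block is channel attention: a global average pool ("squeeze")
followed by a two-layer bottleneck MLP and a sigmoid ("excitation") whose
per-channel weights rescale the input.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import Conv2d, InstanceNorm2d, Linear, Module


class AttentionGate(Module):
    """Additive attention over a skip connection.

    Parameters
    ----------
    skip_ch : channels of the skip feature y.
    gate_ch : channels of the gating signal omega.
    inter_ch : internal channel count of the additive map (default skip_ch // 2).
    """

    def __init__(self, skip_ch: int, gate_ch: int, rng: np.random.Generator,
                 inter_ch: int | None = None):
        super().__init__()
        if inter_ch is None:
            inter_ch = max(skip_ch // 2, 1)
        self.inter_ch = inter_ch
        self.w_y = Conv2d(skip_ch, inter_ch, 1, rng, bias=True)
        self.w_omega = Conv2d(gate_ch, inter_ch, 1, rng, bias=True)
        self.psi = Conv2d(inter_ch, 1, 1, rng, bias=True)

    def coefficients(self, y: Tensor, omega: Tensor) -> Tensor:
        """Attention coefficients beta on y's grid, each strictly in (0, 1)."""
        omega = ag.resize_bilinear(omega, y.shape[2:])
        f = ag.relu(self.w_y(y) + self.w_omega(omega))
        return ag.sigmoid(self.psi(f))

    def forward(self, y: Tensor, omega: Tensor) -> Tensor:
        beta = self.coefficients(y, omega)
        return y * beta  # beta broadcasts over the channel axis


class SEBlock(Module):
    """Squeeze-and-excitation channel re-weighting."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 16):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.reduction = reduction
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def weights(self, x: Tensor) -> Tensor:
        squeezed = ag.mean(x, axis=(2, 3))  # (N, C)
        return ag.sigmoid(self.fc2(ag.relu(self.fc1(squeezed))))

    def forward(self, x: Tensor) -> Tensor:
        w = self.weights(x)
        n, c = w.shape
        return x * ag.reshape(w, (n, c, 1, 1))


class ConvBlock(Module):
    """conv -> norm -> ReLU, twice (plain U-Net stage)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 norm: bool = True):
        super().__init__()
        self.c1 = Conv2d(in_ch, out_ch, 3, rng)
        self.n1 = InstanceNorm2d(out_ch) if norm else None
        self.c2 = Conv2d(out_ch, out_ch, 3, rng)
        self.n2 = InstanceNorm2d(out_ch) if norm else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.c1(x)
        if self.n1 is not None:
            h = self.n1(h)
        h = ag.relu(h)
        h = self.c2(h)
        if self.n2 is not None:
            h = self.n2(h)
        return ag.relu(h)


class ResidualBlock(Module):
    """Two-conv residual stage with a 1x1 projection when channels change."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 norm: bool = True, se: "SEBlock | None" = None):
        super().__init__()
        self.c1 = Conv2d(in_ch, out_ch, 3, rng)
        self.n1 = InstanceNorm2d(out_ch) if norm else None
        self.c2 = Conv2d(out_ch, out_ch, 3, rng)
        self.n2 = InstanceNorm2d(out_ch) if norm else None
        self.proj = Conv2d(in_ch, out_ch, 1, rng, bias=False) if in_ch != out_ch else None
        self.se = se

    def forward(self, x: Tensor) -> Tensor:
        h = self.c1(x)
        if self.n1 is not None:
            h = self.n1(h)
        h = ag.relu(h)
        h = self.c2(h)
        if self.n2 is not None:
            h = self.n2(h)
        if self.se is not None:
            h = self.se(h)
        shortcut = x if self.proj is None else self.proj(x)
        return ag.relu(h + shortcut)
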