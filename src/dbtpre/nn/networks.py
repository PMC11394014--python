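"""Generator and discriminator architectures.

Three interchangeable generators share one encoder--bridge--decoder layout:

* ``U-Net``   — plain double-conv stages, no residual connections.
* ``ResUNet`` — every stage is a residual block.
* ``rSEAG``   — ResUNet plus a squeeze-and-excitation block inside the
  bridge residual stage and an additive attention gate on every skip
  connection, gated by the decoder-side signal entering that skip's
  concatenation.

The discriminator is a PatchGAN: a small strided conv stack emitting a 2-D
map of realness scores rather than a single scalar.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .blocks import AttentionGate, ConvBlock, ResidualBlock, SEBlock
from .layers import Conv2d, InstanceNorm2d, Module, ModuleList

GENERATOR_KINDS = ("rseag", "resunet", "unet")

_ALIASES = {"rseag": "rseag", "resunet": "resunet", "unet": "unet", "u-net": "unet"}


def _canonical_kind(kind: str) -> str:
    k = kind.lower().replace(" ", "")
    if k not in _ALIASES:
        raise ValueError(f"unknown generator kind {kind!r}; expected one of "
                         f"rSEAG, ResUNet, U-Net")
    return _ALIASES[k]


@dataclass
class GeneratorSpec:
    """Declarative generator architecture."""

    kind: str = "rseag"
    depth: int = 4
    base_channels: int = 64
    in_channels: int = 1
    out_channels: int = 1
    norm: str = "instance"
    final_activation: str = "linear"
    se_reduction: int = 16
    max_channel_mult: int = 8

    def __post_init__(self):
        self.kind = _canonical_kind(self.kind)
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.norm not in ("instance", "none"):
            raise ValueError("norm must be 'instance' or 'none'")
        if self.final_activation not in ("linear", "sigmoid"):
            raise ValueError("final_activation must be 'linear' or 'sigmoid'")

    def channels(self, level: int) -> int:
        return self.base_channels * min(2**level, self.max_channel_mult)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "GeneratorSpec":
        return cls(**json.loads(s))


@dataclass
class DiscriminatorSpec:
    """PatchGAN discriminator architecture."""

    base_channels: int = 64
    n_layers: int = 3
    in_channels: int = 1
    norm: str = "instance"

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    return ag.relu(x) - slope * ag.relu(-x)


class Generator(Module):
    """Encoder--bridge--decoder translator over single-channel patches."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        norm = spec.norm == "instance"
        residual = spec.kind in ("resunet", "rseag")
        Block = ResidualBlock if residual else ConvBlock
        d = spec.depth

        enc, downs = [], []
        in_ch = spec.in_channels
        for lvl in range(d):
            out_ch = spec.channels(lvl)
            enc.append(Block(in_ch, out_ch, rng, norm=norm))
            downs.append(Conv2d(out_ch, out_ch, 3, rng, stride=2, padding=1))
            in_ch = out_ch
        self.encoder = ModuleList(enc)
        self.downs = ModuleList(downs)

        bridge_ch = spec.channels(d)
        se = SEBlock(bridge_ch, rng, spec.se_reduction) if spec.kind == "rseag" else None
        if residual:
            self.bridge = ResidualBlock(in_ch, bridge_ch, rng, norm=norm, se=se)
        else:
            self.bridge = ConvBlock(in_ch, bridge_ch, rng, norm=norm)

        ups, dec, gates = [], [], []
        cur = bridge_ch
        for lvl in reversed(range(d)):
            skip_ch = spec.channels(lvl)
            ups.append(Conv2d(cur, skip_ch, 3, rng))
            if spec.kind == "rseag":
                gates.append(AttentionGate(skip_ch, skip_ch, rng))
            dec.append(Block(2 * skip_ch, skip_ch, rng, norm=norm))
            cur = skip_ch
        self.ups = ModuleList(ups)
        self.decoder = ModuleList(dec)
        self.gates = ModuleList(gates)
        self.head = Conv2d(cur, spec.out_channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        h = x
        for block, down in zip(self.encoder, self.downs):
            h = block(h)
            skips.append(h)
            h = down(h)
        h = self.bridge(h)
        for i, (up, dec) in enumerate(zip(self.ups, self.decoder)):
            skip = skips[-(i + 1)]
            h = up(ag.upsample_nearest2d(h, 2))
            h = ag.resize_bilinear(h, skip.shape[2:])
            if len(self.gates):
                skip = self.gates[i](skip, h)  # gated by the decoder-side signal
            h = dec(ag.concat([skip, h], axis=1))
        out = self.head(h)
        if self.spec.final_activation == "sigmoid":
            out = ag.sigmoid(out)
        return out

    # -- structural census (used by tests and reports) ------------------
    def count_attention_gates(self) -> int:
        return sum(1 for m in self.modules() if isinstance(m, AttentionGate))

    def count_se_blocks(self) -> int:
        return sum(1 for m in self.modules() if isinstance(m, SEBlock))

    def translate(self, images: np.ndarray) -> np.ndarray:
        """Run a (N, H, W) or (H, W) array through the network, no grad kept."""
        arr = np.asarray(images, dtype=np.float64)
        single = arr.ndim == 2
        if single:
            arr = arr[None]
        out = self.forward(Tensor(arr[:, None])).data[:, 0]
        return out[0] if single else out


class PatchDiscriminator(Module):
    """PatchGAN: strided conv stack -> 2-D realness score map."""

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        norm = spec.norm == "instance"
        convs, norms = [], []
        in_ch = spec.in_channels
        ch = spec.base_channels
        for i in range(spec.n_layers):
            convs.append(Conv2d(in_ch, ch, 4, rng, stride=2, padding=1))
            norms.append(InstanceNorm2d(ch) if (norm and i > 0) else None)
            in_ch, ch = ch, min(ch * 2, spec.base_channels * 8)
        self.convs = ModuleList(convs)
        self._norms = [n for n in norms]  # may contain None
        for i, n in enumerate(norms):
            if n is not None:
                setattr(self, f"norm{i}", n)
        self.head = Conv2d(in_ch, 1, 4, rng, stride=1, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        for conv, n in zip(self.convs, self._norms):
            h = conv(h)
            if n is not None:
                h = n(h)
            h = leaky_relu(h)
        return self.head(h)

    def score(self, images: np.ndarray) -> np.ndarray:
        arr = np.asarray(images, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
        return self.forward(Tensor(arr[:, None])).data[:, 0]


def build_generator(spec: GeneratorSpec, seed: int) -> Generator:
    """Deterministically initialized generator for a given seed."""
    return Generator(spec, np.random.default_rng(seed))


def build_discriminator(spec: DiscriminatorSpec, seed: int) -> PatchDiscriminator:
    return PatchDiscriminator(spec, np.random.default_rng(seed))
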