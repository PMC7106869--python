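"""The four translation networks.

- ``UNet`` (G_S): 10-block encoder-decoder with skip concatenation — five
  stride-2 conv blocks (kernel 3, padding 1) down, five stride-2 transposed
  conv blocks (kernel 4, padding 1) up, batch-norm + relu per block, tanh (or
  raw logits, for segmentation pretraining) on the last block.
- ``Decoder`` (S2U parent / decoder half of G_U): 4 transposed-conv blocks
  from a small latent grid up to image size, tanh at the end.
- ``Encoder``: conv blocks mapping a sketch onto the decoder's latent grid.
- ``Discriminator`` (D_S, D_U): 5 stride-2 conv blocks on the channel-wise
  concatenation of candidate and condition, sigmoid patch score map.

``WeightState`` bundles a network's parameter arrays with its spec and a
provenance tag (random-init / parent / transferred) and round-trips through
a single checkpoint file bit-exactly.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from . import nn

__all__ = [
    "UNetSpec",
    "DecoderSpec",
    "EncoderSpec",
    "DiscriminatorSpec",
    "WeightState",
    "UNet",
    "Decoder",
    "Encoder",
    "ComposedS2U",
    "Discriminator",
    "build_unet_generator",
    "build_decoder_generator",
    "build_encoder",
    "build_discriminator",
    "attach_encoder",
    "save_weight_state",
    "load_weight_state",
    "build_from_state",
]

_SPEC_TYPES: dict[str, type] = {}


def _register(cls):
    _SPEC_TYPES[cls.__name__] = cls
    return cls


@_register
@dataclass(frozen=True)
class UNetSpec:
    in_channels: int = 1
    out_channels: int = 1
    base_channels: int = 32
    max_channels: int = 256
    final_activation: str = "tanh"  # "tanh" | "none" (segmentation logits)

    @property
    def down_channels(self) -> list[int]:
        return [
            min(self.base_channels * 2**i, self.max_channels) for i in range(5)
        ]


@_register
@dataclass(frozen=True)
class DecoderSpec:
    latent_channels: int = 64
    latent_size: int = 4  # spatial side of the latent grid
    out_channels: int = 1
    base_channels: int = 32
    n_blocks: int = 4

    @property
    def image_size(self) -> int:
        return self.latent_size * 2**self.n_blocks

    @property
    def block_channels(self) -> list[int]:
        # latent -> base*4 -> base*2 -> base -> out  (for the default 4 blocks)
        chans = [self.base_channels * 2**i for i in range(self.n_blocks - 2, -1, -1)]
        return [self.latent_channels] + chans + [self.out_channels]


@_register
@dataclass(frozen=True)
class EncoderSpec:
    in_channels: int = 1
    latent_channels: int = 64
    latent_size: int = 4
    image_size: int = 64
    base_channels: int = 8

    @property
    def n_blocks(self) -> int:
        ratio = self.image_size // self.latent_size
        n = int(np.log2(ratio))
        if 2**n != ratio:
            raise ValueError(
                f"image_size/latent_size must be a power of two, got {ratio}"
            )
        return n


@_register
@dataclass(frozen=True)
class DiscriminatorSpec:
    in_channels: int = 2  # candidate + condition, channel-concatenated
    base_channels: int = 16
    max_channels: int = 128
    n_blocks: int = 5


@dataclass
class WeightState:
    """Named parameter arrays + the spec they belong to + provenance."""

    spec: object
    arrays: dict[str, np.ndarray]
    provenance: str = "random-init"  # random-init | parent | transferred

    def copy(self) -> "WeightState":
        return WeightState(
            self.spec, {k: v.copy() for k, v in self.arrays.items()}, self.provenance
        )


# ---------------------------------------------------------------------------
# modules


class UNet(nn.Module):
    """10-block U-Net; output spatial size equals input size for any
    height/width divisible by 32."""

    def __init__(self, spec: UNetSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x01]))
        ch = spec.down_channels  # e.g. [32, 64, 128, 256, 256]
        self.down = []
        prev = spec.in_channels
        for i, c in enumerate(ch):
            block = nn.Sequential(
                nn.Conv2d(prev, c, 3, stride=2, padding=1, rng=rng),
                nn.BatchNorm2d(c),
                nn.ReLU(),
            )
            self.down.append(block)
            self._children[f"down{i}"] = block
            prev = c
        self.up = []
        # up block i consumes concat(previous up output, skip from down[3-i])
        # except the first (bottleneck only) and produces ch[::-1] widths.
        up_out = [ch[3], ch[2], ch[1], ch[0], spec.out_channels]
        in_ch = ch[4]
        for i, c in enumerate(up_out):
            layers = [nn.ConvTranspose2d(in_ch, c, 4, stride=2, padding=1, rng=rng)]
            if i < 4:
                layers += [nn.BatchNorm2d(c), nn.ReLU()]
            elif spec.final_activation == "tanh":
                layers += [nn.Tanh()]
            block = nn.Sequential(*layers)
            self.up.append(block)
            self._children[f"up{i}"] = block
            if i < 4:
                in_ch = c + ch[3 - i]  # concatenated skip
        self._skip_mask: list[bool] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        h, w = x.shape[2:]
        for dim, size in (("height", h), ("width", w)):
            if size % 32 != 0:
                raise ValueError(f"{dim} must be divisible by 32, got {size}")
        skips = []
        for block in self.down:
            x = block(x)
            skips.append(x)
        self._skip_channels = []
        for i, block in enumerate(self.up):
            x = block(x)
            if i < 4:
                skip = skips[3 - i]
                if self._skip_mask is not None and not self._skip_mask[i]:
                    skip = np.zeros_like(skip)
                self._skip_channels.append((x.shape[1], skip.shape[1]))
                x = np.concatenate([x, skip], axis=1)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dskips = [None] * 5
        for i in range(4, -1, -1):
            if i < 4:
                n_up, _ = self._skip_channels[i]
                dskips[3 - i] = dy[:, n_up:]
                dy = dy[:, :n_up]
            dy = self.up[i].backward(dy)
        for i in range(4, -1, -1):
            if dskips[i] is not None:
                dy = dy + dskips[i]
            dy = self.down[i].backward(dy)
        return dy


class Decoder(nn.Module):
    """DCGAN-style decoder: latent (C, s, s) grid -> image, tanh output."""

    def __init__(self, spec: DecoderSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x02]))
        chans = spec.block_channels
        layers: list[nn.Module] = []
        for i in range(spec.n_blocks):
            layers.append(
                nn.ConvTranspose2d(chans[i], chans[i + 1], 4, stride=2, padding=1, rng=rng)
            )
            if i < spec.n_blocks - 1:
                layers += [nn.BatchNorm2d(chans[i + 1]), nn.ReLU()]
            else:
                layers.append(nn.Tanh())
        self.body = nn.Sequential(*layers)
        self._children["body"] = self.body

    def forward(self, z: np.ndarray) -> np.ndarray:
        s = self.spec
        expected = (s.latent_channels, s.latent_size, s.latent_size)
        if z.shape[1:] != expected:
            trace = " -> ".join(
                str(s.latent_size * 2**i) for i in range(s.n_blocks + 1)
            )
            raise ValueError(
                f"latent shape {z.shape[1:]} != {expected}; block sizes {trace}"
            )
        return self.body(z)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.body.backward(dy)


class Encoder(nn.Module):
    """Conv blocks (kernel 3, stride 2, padding 1) sketch -> latent grid."""

    def __init__(self, spec: EncoderSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x03]))
        n = spec.n_blocks
        chans = [spec.in_channels] + [
            min(spec.base_channels * 2**i, spec.latent_channels) for i in range(n - 1)
        ] + [spec.latent_channels]
        layers: list[nn.Module] = []
        for i in range(n):
            layers += [
                nn.Conv2d(chans[i], chans[i + 1], 3, stride=2, padding=1, rng=rng),
                nn.BatchNorm2d(chans[i + 1]),
                nn.ReLU(),
            ]
        self.body = nn.Sequential(*layers)
        self._children["body"] = self.body

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] != self.spec.image_size or x.shape[3] != self.spec.image_size:
            raise ValueError(
                f"encoder expects {self.spec.image_size}px input, got {x.shape[2:]}"
            )
        return self.body(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.body.backward(dy)


class ComposedS2U(nn.Module):
    """G_U = decoder(encoder(sketch)); the sketch replaces random latent input."""

    def __init__(self, encoder: Encoder, decoder: Decoder):
        super().__init__()
        es, ds = encoder.spec, decoder.spec
        if (es.latent_channels, es.latent_size) != (ds.latent_channels, ds.latent_size):
            raise ValueError(
                f"encoder latent ({es.latent_channels},{es.latent_size}) != "
                f"decoder latent ({ds.latent_channels},{ds.latent_size})"
            )
        self.encoder, self.decoder = encoder, decoder
        self._children["encoder"] = encoder
        self._children["decoder"] = decoder

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.decoder(self.encoder(x))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.encoder.backward(self.decoder.backward(dy))


class Discriminator(nn.Module):
    """Patch discriminator on concat(candidate, condition); sigmoid score map."""

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x04]))
        layers: list[nn.Module] = []
        prev = spec.in_channels
        for i in range(spec.n_blocks):
            if i < spec.n_blocks - 1:
                c = min(spec.base_channels * 2**i, spec.max_channels)
                layers.append(nn.Conv2d(prev, c, 3, stride=2, padding=1, rng=rng))
                if i > 0:
                    # no normalisation on the input block: with batch size 1 it
                    # would act as instance norm and erase the global intensity
                    # level, which the discriminator must be able to judge
                    layers.append(nn.BatchNorm2d(c))
                layers.append(nn.ReLU())
                prev = c
            else:
                layers += [
                    nn.Conv2d(prev, 1, 3, stride=2, padding=1, rng=rng),
                    nn.Sigmoid(),
                ]
        self.body = nn.Sequential(*layers)
        self._children["body"] = self.body

    def forward(self, candidate: np.ndarray, condition: np.ndarray | None = None):
        if condition is not None:
            if candidate.shape != condition.shape:
                raise ValueError(
                    f"candidate {candidate.shape} and condition {condition.shape} differ"
                )
            x = np.concatenate([candidate, condition], axis=1)
        else:
            x = candidate
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"discriminator expects {self.spec.in_channels} channels, got {x.shape[1]}"
            )
        return self.body(x)

    def __call__(self, candidate, condition=None):
        return self.forward(candidate, condition)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.body.backward(dy)


# ---------------------------------------------------------------------------
# builders + weight state


def _snapshot(net: nn.Module, spec, provenance: str = "random-init") -> WeightState:
    return WeightState(spec=spec, arrays=net.state_dict(), provenance=provenance)


def build_unet_generator(spec: UNetSpec, seed: int = 0):
    net = UNet(spec, seed)
    return net, _snapshot(net, spec)


def build_decoder_generator(spec: DecoderSpec, seed: int = 0):
    net = Decoder(spec, seed)
    return net, _snapshot(net, spec)


def build_encoder(spec: EncoderSpec, seed: int = 0):
    net = Encoder(spec, seed)
    return net, _snapshot(net, spec)


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0):
    net = Discriminator(spec, seed)
    return net, _snapshot(net, spec)


def attach_encoder(encoder: Encoder, parent_decoder: WeightState) -> ComposedS2U:
    """Attach a sketch encoder in front of a pretrained decoder.

    The composite's decoder parameters are bit-identical to the parent
    checkpoint at attachment time, and its decoder sub-state carries the
    parent's provenance.
    """
    if not isinstance(parent_decoder.spec, DecoderSpec):
        raise TypeError("parent_decoder must carry a DecoderSpec")
    decoder = Decoder(parent_decoder.spec)
    decoder.load_state_dict(parent_decoder.arrays, strict=True)
    composed = ComposedS2U(encoder, decoder)
    composed.decoder_provenance = parent_decoder.provenance
    return composed


def weight_state_of(net: nn.Module, provenance: str = "random-init") -> WeightState:
    return _snapshot(net, net.spec if hasattr(net, "spec") else None, provenance)


def save_weight_state(state: WeightState, path: str | os.PathLike) -> None:
    """Single-file checkpoint: npz of arrays + embedded JSON spec header."""
    header = {
        "spec_type": type(state.spec).__name__,
        "spec": asdict(state.spec) if state.spec is not None else None,
        "provenance": state.provenance,
    }
    buf = io.BytesIO()
    np.savez(
        buf,
        __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        **state.arrays,
    )
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_weight_state(path: str | os.PathLike, expect_spec: object | None = None) -> WeightState:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        arrays = {k: data[k].copy() for k in data.files if k != "__header__"}
    spec_cls = _SPEC_TYPES.get(header["spec_type"])
    spec = spec_cls(**header["spec"]) if spec_cls and header["spec"] is not None else None
    if expect_spec is not None and spec != expect_spec:
        raise ValueError(
            f"checkpoint spec mismatch: file has {spec!r}, expected {expect_spec!r}"
        )
    return WeightState(spec=spec, arrays=arrays, provenance=header["provenance"])


_NET_FOR_SPEC = {
    "UNetSpec": UNet,
    "DecoderSpec": Decoder,
    "EncoderSpec": Encoder,
    "DiscriminatorSpec": Discriminator,
}


def build_from_state(state: WeightState) -> nn.Module:
    """Reconstruct a network from a WeightState (spec header drives the type)."""
    cls = _NET_FOR_SPEC[type(state.spec).__name__]
    net = cls(state.spec)
    net.load_state_dict(state.arrays, strict=True)
    return net
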