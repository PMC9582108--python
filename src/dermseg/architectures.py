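"""The four segmentation networks and their building blocks.

Attention Squeeze U-Net is a parameter-light encoder-decoder: a stride-2
stem convolution and max-pooled *fire* stages contract the input, and four
attention-gated upsampling blocks expand it back, followed by a
nearest-neighbour upsampling stage and two plain convolutions.  Fire blocks
(a 1x1 "squeeze" convolution feeding a two-branch inception of 3x3 and 1x1
convolutions, concatenated) are what keep the parameter count near 2.5
million instead of U-Net's ~31 million.  Baselines U-Net, Attention U-Net
and Squeeze U-Net share the same interface for comparison.

The per-stage channel schedule is a package design choice exposed in
:data:`SQUEEZE_SCHEDULE` / :data:`UNET_FILTERS`; the published trainable
parameter counts of the reference models are the yardstick it was tuned
against (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import functional as F
from .nn.layers import Conv2d, ConvTranspose2d, Module, ModuleList
from .nn.tensor import Tensor, as_tensor, concat, no_grad, relu, sigmoid, softmax

ARCHITECTURES = ("unet", "attention_unet", "squeeze_unet", "attention_squeeze_unet")

#: Channel schedule of the squeeze variants.  Encoder: 64-channel stride-2
#: stem, then four max-pooled fire stages; squeeze channels are
#: output_channels / squeeze_ratio.  The decoder mirrors the encoder.
SQUEEZE_SCHEDULE: dict = {
    "stem_channels": 64,
    "stage_channels": (128, 256, 512, 1024),
    "fires_per_stage": 2,
    "squeeze_ratio": 8,
    "head_channels": (32, 16),
    "attention_ratio": 8,   # gate intermediate channels = skip channels / ratio
}

#: Per-stage filters of the classic U-Net baseline (two 3x3 convs per stage).
UNET_FILTERS = (64, 128, 256, 512, 1024)


@dataclass(frozen=True)
class FireSpec:
    """Squeeze (C_S) and output (C_O) channel counts of a fire block."""

    squeeze_channels: int
    output_channels: int

    def __post_init__(self):
        if self.squeeze_channels <= 0:
            raise ValueError("squeeze_channels must be positive")
        if self.output_channels <= 0 or self.output_channels % 2:
            raise ValueError(
                f"output_channels must be a positive even number (the two "
                f"inception branches carry half each), got {self.output_channels}")


@dataclass(frozen=True)
class NetworkSpec:
    """Everything needed to build one of the four networks deterministically."""

    architecture: str = "attention_squeeze_unet"
    height: int = 384
    width: int = 512
    in_channels: int = 3
    num_classes: int = 2
    seed: int = 0
    schedule: dict = field(default_factory=lambda: dict(SQUEEZE_SCHEDULE))

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}")
        div = required_divisor(self.architecture)
        if self.height % div or self.width % div:
            raise ValueError(
                f"{self.architecture} needs input height and width divisible by "
                f"{div}; got {self.height}x{self.width}")


def required_divisor(architecture: str) -> int:
    """Power of two the input size must be divisible by (downsampling depth)."""
    return 32 if "squeeze" in architecture else 16


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class FireBlock(Module):
    """1x1 squeeze conv -> parallel 3x3 and 1x1 convs -> channel concat."""

    def __init__(self, in_channels: int, spec: FireSpec, rng: np.random.Generator):
        half = spec.output_channels // 2
        self.squeeze = Conv2d(in_channels, spec.squeeze_channels, 1, rng)
        self.expand3 = Conv2d(spec.squeeze_channels, half, 3, rng)
        self.expand1 = Conv2d(spec.squeeze_channels, half, 1, rng)

    def forward(self, x) -> Tensor:
        s = relu(self.squeeze(as_tensor(x)))
        return concat([relu(self.expand3(s)), relu(self.expand1(s))], axis=1)


class TransposedFireBlock(Module):
    """1x1 transposed conv (optionally stride 2) -> parallel 2x2 and 1x1 convs."""

    def __init__(self, in_channels: int, spec: FireSpec, rng: np.random.Generator,
                 stride: int = 2):
        half = spec.output_channels // 2
        self.stride = stride
        self.squeeze = ConvTranspose2d(in_channels, spec.squeeze_channels, 1, rng,
                                       stride=stride)
        self.expand2 = Conv2d(spec.squeeze_channels, half, 2, rng)
        self.expand1 = Conv2d(spec.squeeze_channels, half, 1, rng)

    def forward(self, x, out_hw: tuple[int, int] | None = None) -> Tensor:
        s = relu(self.squeeze(as_tensor(x), out_hw=out_hw))
        return concat([relu(self.expand2(s)), relu(self.expand1(s))], axis=1)


class AttentionBlock(Module):
    """Additive attention gate: weight skip features by a learned [0,1] map.

    g (gating, already at x's spatial size) and x are each projected by 1x1
    convolutions to a common intermediate channel count, summed, passed
    through ReLU and a 1x1 convolution down to one channel, and squashed by
    a sigmoid; the resulting map multiplies x pixel-wise.
    """

    def __init__(self, g_channels: int, x_channels: int, inter_channels: int,
                 rng: np.random.Generator):
        self.project_g = Conv2d(g_channels, inter_channels, 1, rng)
        self.project_x = Conv2d(x_channels, inter_channels, 1, rng)
        self.psi = Conv2d(inter_channels, 1, 1, rng)

    def attention_map(self, g, x) -> Tensor:
        g, x = as_tensor(g), as_tensor(x)
        if g.data.shape[2:] != x.data.shape[2:]:
            raise ValueError(
                f"attention inputs must share spatial size; got g {g.data.shape[2:]} "
                f"vs x {x.data.shape[2:]}")
        return sigmoid(self.psi(relu(self.project_g(g) + self.project_x(x))))

    def forward(self, g, x) -> Tensor:
        return as_tensor(x) * self.attention_map(g, x)


class UpsamplingBlock(Module):
    """Decoder unit: upsample g, (optionally) gate the skip, fuse with a fire.

    ghat = stride-2 transposed-fire of g, brought to the skip's spatial size;
    a = attention(ghat, x) when gating is enabled, else a = x;
    output = fire(concat(a, ghat)).
    """

    def __init__(self, g_channels: int, x_channels: int, out_channels: int,
                 rng: np.random.Generator, attention: bool,
                 squeeze_ratio: int = 8, attention_ratio: int = 8):
        self.up = TransposedFireBlock(
            g_channels, FireSpec(max(x_channels // squeeze_ratio, 1), x_channels),
            rng, stride=2)
        self.attention = (AttentionBlock(x_channels, x_channels,
                                         max(x_channels // attention_ratio, 1), rng)
                          if attention else None)
        self.fuse = FireBlock(2 * x_channels,
                              FireSpec(max(out_channels // squeeze_ratio, 1),
                                       out_channels), rng)

    def forward(self, g, x) -> Tensor:
        g, x = as_tensor(g), as_tensor(x)
        gh, gw = g.data.shape[2:]
        xh, xw = x.data.shape[2:]
        if (xh, xw) != (2 * gh, 2 * gw):
            raise ValueError(
                f"skip input must have twice the gating signal's spatial size; "
                f"got g {(gh, gw)} vs x {(xh, xw)}")
        ghat = self.up(g, out_hw=(xh, xw))
        a = self.attention(ghat, x) if self.attention is not None else x
        return self.fuse(concat([a, ghat], axis=1))


class _ConvRelu(Module):
    def __init__(self, cin, cout, k, rng, stride=1):
        self.conv = Conv2d(cin, cout, k, rng, stride=stride)

    def forward(self, x):
        return relu(self.conv(x))


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

class SqueezeSegNet(Module):
    """Squeeze U-Net, optionally with attention gates in the decoder."""

    def __init__(self, spec: NetworkSpec, attention: bool):
        sched = spec.schedule
        rng = np.random.default_rng(spec.seed)
        ratio = sched["squeeze_ratio"]
        stages = sched["stage_channels"]
        stem_ch = sched["stem_channels"]
        self.spec = spec

        self.stem = _ConvRelu(spec.in_channels, stem_ch, 3, rng, stride=2)
        self.stages = ModuleList()
        cin = stem_ch
        for co in stages:
            fires = ModuleList()
            for _ in range(sched["fires_per_stage"]):
                fires.append(FireBlock(cin, FireSpec(co // ratio, co), rng))
                cin = co
            self.stages.append(fires)

        self.ups = ModuleList()
        skip_channels = (stem_ch,) + tuple(stages[:-1])  # /2, /4, /8, /16
        g_ch = stages[-1]
        for x_ch in reversed(skip_channels):
            self.ups.append(UpsamplingBlock(
                g_ch, x_ch, x_ch, rng, attention=attention,
                squeeze_ratio=ratio, attention_ratio=sched["attention_ratio"]))
            g_ch = x_ch

        h1, h2 = sched["head_channels"]
        self.head1 = _ConvRelu(stem_ch, h1, 3, rng)
        self.head2 = _ConvRelu(h1, h2, 3, rng)
        self.classifier = Conv2d(h2, spec.num_classes, 1, rng)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        skips = []
        h = self.stem(x)
        skips.append(h)
        for i, fires in enumerate(self.stages):
            h = F.maxpool2d(h, 2)
            for fire in fires:
                h = fire(h)
            if i < len(self.stages) - 1:
                skips.append(h)
        for up, skip in zip(self.ups, reversed(skips)):
            h = up(h, skip)
        h = self.head1(h)
        h = F.upsample_nearest2d(h, 2)
        h = self.head2(h)
        return softmax(self.classifier(h), axis=1)


class _UNetStage(Module):
    def __init__(self, cin, cout, rng):
        self.conv1 = _ConvRelu(cin, cout, 3, rng)
        self.conv2 = _ConvRelu(cout, cout, 3, rng)

    def forward(self, x):
        return self.conv2(self.conv1(x))


class UNet(Module):
    """Classic U-Net, optionally with attention-gated skips."""

    def __init__(self, spec: NetworkSpec, attention: bool):
        rng = np.random.default_rng(spec.seed)
        filters = UNET_FILTERS
        self.spec = spec
        self.enc = ModuleList()
        cin = spec.in_channels
        for f in filters[:-1]:
            self.enc.append(_UNetStage(cin, f, rng))
            cin = f
        self.bridge = _UNetStage(cin, filters[-1], rng)

        self.upconvs = ModuleList()
        self.gates = ModuleList()
        self.dec = ModuleList()
        g_ch = filters[-1]
        for f in reversed(filters[:-1]):
            self.upconvs.append(ConvTranspose2d(g_ch, f, 2, rng, stride=2))
            if attention:
                self.gates.append(AttentionBlock(f, f, max(f // 2, 1), rng))
            self.dec.append(_UNetStage(2 * f, f, rng))
            g_ch = f
        self.attention = attention
        self.classifier = Conv2d(filters[0], spec.num_classes, 1, rng)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        skips = []
        h = x
        for stage in self.enc:
            h = stage(h)
            skips.append(h)
            h = F.maxpool2d(h, 2)
        h = self.bridge(h)
        for i, skip in enumerate(reversed(skips)):
            h = self.upconvs[i](h, out_hw=skip.data.shape[2:])
            gated = self.gates[i](h, skip) if self.attention else skip
            h = self.dec[i](concat([gated, h], axis=1))
        return softmax(self.classifier(h), axis=1)


def build_network(spec: NetworkSpec) -> Module:
    """Construct the requested architecture with seeded Glorot initialisation."""
    if spec.architecture == "unet":
        return UNet(spec, attention=False)
    if spec.architecture == "attention_unet":
        return UNet(spec, attention=True)
    if spec.architecture == "squeeze_unet":
        return SqueezeSegNet(spec, attention=False)
    if spec.architecture == "attention_squeeze_unet":
        return SqueezeSegNet(spec, attention=True)
    raise ValueError(f"unknown architecture {spec.architecture!r}")


def count_parameters(model: Module) -> int:
    """Total number of trainable scalar parameters."""
    return int(sum(p.data.size for p in model.parameters()))


def predict_probs(model: Module, images: np.ndarray) -> np.ndarray:
    """Inference helper: (N,H,W,3) or (H,W,3) in [0,1] -> (N,H,W,2) softmax."""
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[None]
    x = images.transpose(0, 3, 1, 2)
    with no_grad():
        probs = build_forward(model, x)
    return probs.transpose(0, 2, 3, 1)


def build_forward(model: Module, x_nchw: np.ndarray) -> np.ndarray:
    """Run a forward pass on an NCHW float array, returning an ndarray."""
    return model(Tensor(x_nchw)).data
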