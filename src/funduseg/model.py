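"""The encoder / dual-attention / decoder segmentation network.

The architecture targets the small, low-contrast lesions of diabetic
retinopathy, where repeated pooling destroys the signal: downsampling uses
a single 2x2 max-pool followed by stride-2 residual bottleneck blocks, the
two deepest encoder maps pass through dual (position + channel)
self-attention before their skip connections, a three-rate dilated block
(rates 1, 2, 5 — chosen to avoid gridding) widens the receptive field at
the bottom, and a U-net-style decoder with bilinear-upsample + conv and
skip concatenation restores full resolution.  The head is a per-pixel
sigmoid over the four lesion classes (multi-label: classes may overlap).

Channel counts double per encoder stage from ``base_channels``; residual
blocks are bottlenecked, with internal width ``out_channels /
bottleneck_ratio``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .io_masks import CLASSES, FundusImage, LesionMaskSet
from .nn import Tensor

__all__ = [
    "ModelConfig",
    "ConvBlock",
    "IdentityBlock",
    "PositionAttention",
    "ChannelAttention",
    "DualAttention",
    "DilatedBlock",
    "EADNet",
    "build_model",
    "predict",
]

#: largest spatial-attention map allowed (N x N affinity grows quadratically)
_MAX_ATTENTION_POSITIONS = 4096


@dataclass
class ModelConfig:
    input_size: int = 512
    in_channels: int = 3
    num_classes: int = 4
    base_channels: int = 64
    encoder_stages: int = 4
    bottleneck_ratio: int = 4
    dilation_rates: tuple[int, int, int] = (1, 2, 5)
    dropout_rate: float = 0.5
    attention_stages: tuple[int, ...] = (3, 4)

    def __post_init__(self):
        if self.input_size % (2 ** self.encoder_stages) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{self.encoder_stages}"
            )
        if any(r < 1 for r in self.dilation_rates):
            raise ValueError(f"dilation rates must be positive, got {self.dilation_rates}")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1], got {self.dropout_rate}")
        for s in self.attention_stages:
            if not 1 <= s <= self.encoder_stages:
                raise ValueError(f"attention stage {s} outside 1..{self.encoder_stages}")
            side = self.input_size // (2 ** s)
            if side * side > _MAX_ATTENTION_POSITIONS:
                raise ValueError(
                    f"attention at stage {s} would need a {side * side}x{side * side} "
                    f"affinity matrix; restrict attention to deeper stages"
                )

    def stage_channels(self, stage: int) -> int:
        return self.base_channels * (2 ** (stage - 1))


def _cbr(in_ch, out_ch, rng, stride=1, dilation=1):
    return nn.Sequential(
        nn.Conv2d(in_ch, out_ch, 3, stride=stride, dilation=dilation, rng=rng),
        nn.BatchNorm2d(out_ch),
        nn.ReLU(),
    )


class ConvBlock(nn.Module):
    """Residual bottleneck block with a projection shortcut.

    Two 3x3 conv-BN-ReLU stages at the internal width, a 3x3 conv-BN
    expansion, plus a 3x3 conv-BN shortcut; the sum passes a final ReLU.
    ``stride`` (applied in the first conv and the shortcut) performs the
    encoder's downsampling in place of pooling.
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1,
                 bottleneck_ratio: int = 4, rng=None):
        super().__init__()
        mid = max(1, out_ch // bottleneck_ratio)
        self.branch = nn.Sequential(
            _cbr(in_ch, mid, rng, stride=stride),
            _cbr(mid, mid, rng),
            nn.Conv2d(mid, out_ch, 3, rng=rng),
            nn.BatchNorm2d(out_ch),
        )
        self.shortcut = nn.Sequential(
            nn.Conv2d(in_ch, out_ch, 3, stride=stride, rng=rng),
            nn.BatchNorm2d(out_ch),
        )
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return (self.branch(x) + self.shortcut(x)).relu()


class IdentityBlock(nn.Module):
    """Residual bottleneck block whose shortcut is the identity.

    Input and output channel counts must match; spatial size is preserved.
    """

    def __init__(self, channels: int, bottleneck_ratio: int = 4, rng=None):
        super().__init__()
        mid = max(1, channels // bottleneck_ratio)
        self.branch = nn.Sequential(
            _cbr(channels, mid, rng),
            _cbr(mid, mid, rng),
            nn.Conv2d(mid, channels, 3, rng=rng),
            nn.BatchNorm2d(channels),
        )

    def forward(self, x: Tensor) -> Tensor:
        return (self.branch(x) + x).relu()


class PositionAttention(nn.Module):
    """Spatial self-attention: each position is re-expressed as a
    softmax-weighted sum over all positions, added back through a
    learnable scale ``gamma`` initialised to zero (so the module starts as
    the identity)."""

    def __init__(self, channels: int, rng=None):
        super().__init__()
        reduced = max(1, channels // 8)
        self.query = nn.Conv2d(channels, reduced, 1, rng=rng)
        self.key = nn.Conv2d(channels, reduced, 1, rng=rng)
        self.value = nn.Conv2d(channels, channels, 1, rng=rng)
        self.gamma = nn.Parameter(np.zeros(1))

    def attention_weights(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        n = H * W
        q = self.query(x).reshape(B, -1, n).swap_last_axes()  # (B, N, Cq)
        k = self.key(x).reshape(B, -1, n)                     # (B, Cq, N)
        return q.matmul(k).softmax(axis=-1)                   # rows sum to 1

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        n = H * W
        attn = self.attention_weights(x)
        v = self.value(x).reshape(B, C, n)
        out = v.matmul(attn.swap_last_axes()).reshape(B, C, H, W)
        return self.gamma * out + x


class ChannelAttention(nn.Module):
    """Channel self-attention: a CxC softmax affinity between flattened
    feature maps re-mixes channels; residual scale ``gamma`` starts at
    zero."""

    def __init__(self, channels: int):
        super().__init__()
        self.gamma = nn.Parameter(np.zeros(1))

    def attention_weights(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        flat = x.reshape(B, C, H * W)
        return flat.matmul(flat.swap_last_axes()).softmax(axis=-1)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        flat = x.reshape(B, C, H * W)
        out = self.attention_weights(x).matmul(flat).reshape(B, C, H, W)
        return self.gamma * out + x


class DualAttention(nn.Module):
    """Sum of position- and channel-attention outputs.

    With both residual scales at zero the module reduces to ``2 * x``
    (each branch passes its input through unchanged and the two are
    summed).
    """

    def __init__(self, channels: int, rng=None):
        super().__init__()
        self.position = PositionAttention(channels, rng=rng)
        self.channel = ChannelAttention(channels)

    def forward(self, x: Tensor) -> Tensor:
        return self.position(x) + self.channel(x)


class DilatedBlock(nn.Module):
    """Three sequential 3x3 dilated conv-BN-ReLU stages.

    With rates (1, 2, 5) the stacked receptive field is 17x17 while
    spatial dimensions are preserved by matching padding.
    """

    def __init__(self, channels: int, rates: tuple[int, int, int] = (1, 2, 5), rng=None):
        super().__init__()
        if any(r < 1 for r in rates):
            raise ValueError(f"dilation rates must be positive, got {rates}")
        self.stages = nn.Sequential(*[_cbr(channels, channels, rng, dilation=r) for r in rates])
        self.rates = tuple(rates)

    @staticmethod
    def receptive_field(rates, kernel_size: int = 3) -> int:
        """Receptive-field side of the stack: r_out = r_in + (k-1)*d."""
        rf = 1
        for d in rates:
            rf += (kernel_size - 1) * d
        return rf

    def forward(self, x: Tensor) -> Tensor:
        return self.stages(x)


class _UpBlock(nn.Module):
    """Bilinear 2x upsample + conv, skip concatenation, dropout, fuse conv."""

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int,
                 dropout_rate: float, rng, drop_rng):
        super().__init__()
        self.up = nn.UpsampleBilinear2d(2)
        self.reduce = _cbr(in_ch, out_ch, rng)
        self.dropout = nn.Dropout2d(dropout_rate, rng=drop_rng)
        self.fuse = _cbr(out_ch + skip_ch, out_ch, rng)

    def forward_with_skip(self, x: Tensor, skip: Tensor) -> Tensor:
        x = self.reduce(self.up(x))
        x = nn.concat([x, skip], axis=1)
        return self.fuse(self.dropout(x))


class EADNet(nn.Module):
    """Encoder / dual-attention / decoder lesion segmentation network."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        drop_rng = np.random.default_rng(rng.integers(2**31))
        b = config.base_channels
        self.stem = _cbr(config.in_channels, b, rng)
        self.pool = nn.MaxPool2d()
        stages = []
        for s in range(2, config.encoder_stages + 1):
            in_ch = config.stage_channels(s - 1)
            out_ch = config.stage_channels(s)
            stages.append(nn.Sequential(
                ConvBlock(in_ch, out_ch, stride=2,
                          bottleneck_ratio=config.bottleneck_ratio, rng=rng),
                IdentityBlock(out_ch, config.bottleneck_ratio, rng=rng),
            ))
        self.stages = nn.ModuleList(stages)
        self.attention = {
            s: DualAttention(config.stage_channels(s), rng=rng)
            for s in sorted(config.attention_stages)
        }
        # registered for parameter discovery (dict values are invisible to Module)
        self._attention_list = nn.ModuleList(list(self.attention.values()))
        deep = config.stage_channels(config.encoder_stages)
        self.dilated = DilatedBlock(deep, config.dilation_rates, rng=rng)
        ups = []
        for s in range(config.encoder_stages, 1, -1):
            ups.append(_UpBlock(config.stage_channels(s), config.stage_channels(s - 1),
                                config.stage_channels(s - 1), config.dropout_rate,
                                rng, drop_rng))
        self.ups = nn.ModuleList(ups)
        self.final_up = nn.UpsampleBilinear2d(2)
        self.final_conv = _cbr(b, b, rng)
        self.head = nn.Conv2d(b, config.num_classes, 3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        maps: dict[int, Tensor] = {}
        h = self.pool(self.stem(x))           # Map1 at H/2
        maps[1] = h
        for i, stage in enumerate(self.stages, start=2):
            h = stage(h)
            maps[i] = h
        for s, attn in self.attention.items():
            maps[s] = attn(maps[s])
        h = self.dilated(maps[cfg.encoder_stages])
        for up, s in zip(self.ups, range(cfg.encoder_stages, 1, -1)):
            h = up.forward_with_skip(h, maps[s - 1])
        h = self.final_conv(self.final_up(h))
        return self.head(h).sigmoid()


def build_model(config: ModelConfig, seed: int = 0) -> EADNet:
    """Construct the network with reproducible initialisation."""
    return EADNet(config, seed=seed)


def predict(network: EADNet, image: FundusImage, threshold: float = 0.5,
            ) -> tuple[LesionMaskSet, dict[str, np.ndarray]]:
    """Run the network on one image; return binarized masks and prob maps."""
    size = network.config.input_size
    if image.shape != (size, size):
        raise ValueError(f"image shape {image.shape} does not match input size {size}")
    was_training = network.training
    network.eval()
    x = Tensor(image.pixels.astype(np.float64).transpose(2, 0, 1)[None] / 255.0)
    probs = network(x).data[0]
    if was_training:
        network.train()
    prob_maps = {cls: probs[i] for i, cls in enumerate(CLASSES)}
    masks = {cls: (prob_maps[cls] >= threshold).astype(np.uint8) for cls in CLASSES}
    return LesionMaskSet(masks, source_id=image.source_id), prob_maps
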