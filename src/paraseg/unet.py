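"""Configurable U-Net encoder-decoder for binary CT segmentation.

The encoder has L levels; level i holds two same-padded 3x3 convolutions
with LeakyReLU and n_base * 2^(i-1) filters, followed (except at the
bottleneck) by 2x2 max pooling with stride 2. The decoder mirrors it with
2x2/stride-2 transposed convolutions, concatenating the matching encoder
feature map (classic skip connections), and ends in a 1x1 convolution to 2
classes and a per-pixel softmax. The predicted mask is the channel argmax,
with exact ties resolved to background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn

__all__ = ["UNetConfig", "SegmentationOutput", "filters_for_level", "build",
           "UNet", "predict", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyper-parameters.

    ``n_base`` is the filter count of the first convolutional level; level i
    uses n_base * 2^(i-1) filters. ``depth`` (L) counts encoder levels
    including the bottleneck, so inputs must have sides divisible by
    2^(L-1). Batch normalization is off by default.
    """

    n_base: int = 32
    depth: int = 5
    in_channels: int = 1
    n_classes: int = 2
    leaky_slope: float = 0.01
    batch_norm: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_base < 1:
            raise ValueError("n_base must be >= 1")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    @property
    def pool_factor(self) -> int:
        return 2 ** (self.depth - 1)


def filters_for_level(n_base: int, i: int) -> int:
    """Filter count at encoder level i (1-based): n_base * 2^(i-1)."""
    if n_base < 1:
        raise ValueError("n_base must be >= 1")
    if i < 1:
        raise ValueError("level index must be >= 1")
    return n_base * 2 ** (i - 1)


@dataclass
class SegmentationOutput:
    """Per-pixel class probabilities and the argmax mask."""

    probabilities: np.ndarray  # (K, H, W), channels sum to 1 per pixel
    predicted_mask: np.ndarray  # (H, W) in {0, 1}


class _ConvBlock:
    """[3x3 conv, (BN), LeakyReLU] x 2 with same padding."""

    def __init__(self, in_ch, out_ch, slope, batch_norm, rng):
        self.layers = []
        for c_in in (in_ch, out_ch):
            self.layers.append(nn.Conv2d(c_in, out_ch, 3, rng))
            if batch_norm:
                self.layers.append(nn.BatchNorm2d(out_ch))
            self.layers.append(nn.LeakyReLU(slope))

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]


class UNet:
    """The assembled network; built via :func:`build`."""

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        L = config.depth
        self.enc_blocks = []
        self.pools = []
        ch = config.in_channels
        for i in range(1, L + 1):
            out = filters_for_level(config.n_base, i)
            self.enc_blocks.append(
                _ConvBlock(ch, out, config.leaky_slope, config.batch_norm, rng))
            ch = out
            if i < L:
                self.pools.append(nn.MaxPool2x2())
        self.upconvs = []
        self.dec_blocks = []
        for i in range(L - 1, 0, -1):
            out = filters_for_level(config.n_base, i)
            self.upconvs.append(nn.ConvTranspose2x2(ch, out, rng))
            self.dec_blocks.append(
                _ConvBlock(2 * out, out, config.leaky_slope, config.batch_norm, rng))
            ch = out
        self.head = nn.Conv2d(ch, config.n_classes, 1, rng)
        self._skip_channels = None

    @property
    def params(self):
        out = []
        for blk in self.enc_blocks + self.dec_blocks:
            out.extend(blk.params)
        for up in self.upconvs:
            out.extend(up.params)
        out.extend(self.head.params)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params)

    def level_filters(self) -> list[int]:
        """Filter counts actually built at each encoder level (introspection)."""
        counts = []
        for blk in self.enc_blocks:
            convs = [l for l in blk.layers if isinstance(l, nn.Conv2d)]
            counts.append(convs[-1].out_ch)
        return counts

    def _check_input(self, x: np.ndarray):
        f = self.config.pool_factor
        h, w = x.shape[-2:]
        if h % f or w % f:
            raise ValueError(
                f"input side {h}x{w} not divisible by 2^(L-1) = {f} for depth "
                f"{self.config.depth}"
            )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits (N, n_classes, H, W) for input (N, in_channels, H, W)."""
        self._check_input(x)
        skips = []
        for i, blk in enumerate(self.enc_blocks):
            x = blk.forward(x, train=train)
            if i < len(self.pools):
                skips.append(x)
                x = self.pools[i].forward(x, train=train)
        for j, (up, blk) in enumerate(zip(self.upconvs, self.dec_blocks)):
            x = up.forward(x, train=train)
            skip = skips[-(j + 1)]
            x = np.concatenate([skip, x], axis=1)
            x = blk.forward(x, train=train)
        return self.head.forward(x, train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        dy = self.head.backward(dlogits)
        dskip_acc = []
        for j in range(len(self.dec_blocks) - 1, -1, -1):
            dy = self.dec_blocks[j].backward(dy)
            n_skip = self.upconvs[j].out_ch
            dskip, dup = dy[:, :n_skip], dy[:, n_skip:]
            dskip_acc.append(dskip)
            dy = self.upconvs[j].backward(np.ascontiguousarray(dup))
        # dskip_acc[k] is the concat-path gradient for encoder level k (0-based)
        for i in range(len(self.enc_blocks) - 1, -1, -1):
            if i < len(self.pools):
                dy = self.pools[i].backward(dy)
                dy = dy + dskip_acc[i]
            dy = self.enc_blocks[i].backward(dy)

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params]

    def set_state(self, state) -> None:
        for (p, _), s in zip(self.params, state):
            p[...] = s


def build(config: UNetConfig) -> UNet:
    """Construct a network from a validated configuration."""
    return UNet(config)


def predict(network: UNet, img: np.ndarray) -> SegmentationOutput:
    """Segment one normalized slice.

    ``img`` must be the fixed-map normalized image in [0, 1]; raw-HU input
    is rejected. Ties in the softmax are resolved to background (class 0).
    """
    img = np.asarray(img, dtype=np.float32)
    if img.min() < -1e-6 or img.max() > 1.0 + 1e-6:
        raise ValueError(
            f"input not normalized to [0, 1] (range [{img.min():.1f}, "
            f"{img.max():.1f}]); apply dataset.normalize_hu first"
        )
    x = img[None, None]
    logits = network.forward(x, train=False)
    probs = nn.softmax(logits, axis=1)[0]
    # np.argmax returns the first maximum, so exact ties go to background
    mask = np.argmax(probs, axis=0)
    return SegmentationOutput(probs, mask.astype(np.uint8))


def save_checkpoint(network: UNet, path) -> None:
    """Save weights with the config embedded (npz + JSON header)."""
    path = Path(path)
    arrays = {f"p{i}": p for i, (p, _) in enumerate(network.params)}
    np.savez(path, __config__=json.dumps(asdict(network.config)), **arrays)


def load_checkpoint(path) -> UNet:
    data = np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz")
                   else path, allow_pickle=False)
    config = UNetConfig(**json.loads(str(data["__config__"])))
    net = build(config)
    for i, (p, _) in enumerate(net.params):
        p[...] = data[f"p{i}"]
    return net
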