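"""Encoder-decoder (U-Net style) segmentation network with a residual encoder.

The encoder is a stack of residual stages (each stage halves resolution and
raises channel count), the decoder mirrors it with nearest-neighbour
upsampling and skip-connection concatenation, and a 1x1 head produces a
single-channel logit map at input resolution.  Presets scale the same
topology from a test-sized network up to a 34-layer-style residual encoder.
"""

from __future__ import annotations

import numpy as np

from .layers import Adam, BatchNorm2d, Conv2d, Module, Param, ReLU, Upsample2x

#: encoder presets: (stage channels, residual blocks per stage, decoder mode)
#: a zero-block stage passes its input through and only contributes a skip
PRESETS: dict[str, tuple[tuple[int, ...], tuple[int, ...], str]] = {
    # small enough to train on a CPU in NumPy within minutes: the full-res
    # stage is the stem alone and the decoder reduces channels with a 1x1
    # conv before the 3x3 refinement ("bottleneck")
    "tiny": ((8, 16, 32), (0, 1, 1), "bottleneck"),
    "small": ((16, 32, 64), (1, 1, 1), "standard"),
    # the 3/4/6/3 residual stage pattern of a 34-layer residual encoder
    "resnet34": ((64, 64, 128, 256, 512), (1, 3, 4, 6, 3), "standard"),
}


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class ConvBNReLU(Module):
    def __init__(self, in_ch, out_ch, kernel=3, stride=1, rng=None, dtype=np.float32):
        self.conv = Conv2d(in_ch, out_ch, kernel, stride, bias=False, rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(out_ch, dtype=dtype)
        self.relu = ReLU()

    def forward(self, x, training=True):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, training), training), training)

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))


class ResidualBlock(Module):
    """conv-bn-relu-conv-bn plus (projected) identity, then ReLU."""

    def __init__(self, in_ch, out_ch, stride=1, rng=None, dtype=np.float32):
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride, bias=False, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(out_ch, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, 3, 1, bias=False, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(out_ch, dtype=dtype)
        if stride != 1 or in_ch != out_ch:
            self.short_conv = Conv2d(in_ch, out_ch, 1, stride, bias=False, rng=rng, dtype=dtype)
            self.short_bn = BatchNorm2d(out_ch, dtype=dtype)
        else:
            self.short_conv = None
            self.short_bn = None
        self._mask = None

    def forward(self, x, training=True):
        main = self.bn1.forward(self.conv1.forward(x, training), training)
        main = self.relu1.forward(main, training)
        main = self.bn2.forward(self.conv2.forward(main, training), training)
        if self.short_conv is not None:
            short = self.short_bn.forward(self.short_conv.forward(x, training), training)
        else:
            short = x
        y = main + short
        if training:
            self._mask = y > 0
            return y * self._mask
        return np.maximum(y, 0.0)

    def backward(self, dy):
        dy = dy * self._mask
        dmain = self.conv1.backward(self.bn1.backward(
            self.relu1.backward(self.conv2.backward(self.bn2.backward(dy)))))
        if self.short_conv is not None:
            dshort = self.short_conv.backward(self.short_bn.backward(dy))
        else:
            dshort = dy
        return dmain + dshort


class DecoderBlock(Module):
    """Upsample, concatenate the encoder skip, refine with two conv units."""

    def __init__(self, in_ch, skip_ch, out_ch, mode="standard", rng=None, dtype=np.float32):
        self.up = Upsample2x()
        if mode == "bottleneck":  # 1x1 channel fusion, then one 3x3 refinement
            self.convs = [ConvBNReLU(in_ch + skip_ch, out_ch, kernel=1, rng=rng, dtype=dtype),
                          ConvBNReLU(out_ch, out_ch, rng=rng, dtype=dtype)]
        else:  # two 3x3 conv units, classic U-Net decoder
            self.convs = [ConvBNReLU(in_ch + skip_ch, out_ch, rng=rng, dtype=dtype),
                          ConvBNReLU(out_ch, out_ch, rng=rng, dtype=dtype)]
        self.in_ch = in_ch

    def forward(self, x, skip, training=True):
        x = self.up.forward(x, training)
        x = np.concatenate([x, skip], axis=3)
        for conv in self.convs:
            x = conv.forward(x, training)
        return x

    def backward(self, dy):
        for conv in reversed(self.convs):
            dy = conv.backward(dy)
        dx = self.up.backward(dy[..., :self.in_ch])
        dskip = dy[..., self.in_ch:]
        return dx, dskip


class ResidualUNet(Module):
    """The segmentation network: residual encoder, skip-connected decoder,
    single-channel logit head.

    Parameters
    ----------
    in_channels:
        Input channels (3 after grayscale replication for the channel-wise
        normalisation scheme).
    preset:
        One of ``"tiny"``, ``"small"``, ``"resnet34"``; or pass ``channels``
        and ``blocks`` explicitly.
    """

    def __init__(self, in_channels: int = 3, preset: str = "tiny",
                 channels: tuple[int, ...] | None = None,
                 blocks: tuple[int, ...] | None = None,
                 decoder_mode: str = "standard",
                 rng_seed: int = 0, dtype=np.float32):
        if channels is None or blocks is None:
            if preset not in PRESETS:
                raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
            channels, blocks, decoder_mode = PRESETS[preset]
        if len(channels) != len(blocks):
            raise ValueError("channels and blocks must have equal length")
        rng = np.random.default_rng(rng_seed)
        self.channels = tuple(channels)
        self.downsample_factor = 2 ** (len(channels) - 1)

        self.stem = ConvBNReLU(in_channels, channels[0], rng=rng, dtype=dtype)
        self.stages: list[list[ResidualBlock]] = []
        prev = channels[0]
        for i, (ch, nb) in enumerate(zip(channels, blocks)):
            if i > 0 and nb < 1:
                raise ValueError("only the first stage may have zero blocks")
            stage = []
            for b in range(nb):
                stride = 2 if (i > 0 and b == 0) else 1
                stage.append(ResidualBlock(prev, ch, stride, rng=rng, dtype=dtype))
                prev = ch
            self.stages.append(stage)
        self.decoders: list[DecoderBlock] = [
            DecoderBlock(channels[i + 1], channels[i], channels[i],
                         mode=decoder_mode, rng=rng, dtype=dtype)
            for i in reversed(range(len(channels) - 1))
        ]
        self.head = Conv2d(channels[0], 1, kernel=1, rng=rng, dtype=dtype)

    # -- flattened module list for params/buffers discovery -----------------
    def _modules(self):
        yield self.stem
        for st in self.stages:
            yield from st
        yield from self.decoders
        yield self.head

    def params(self):
        out = []
        for m in self._modules():
            out.extend(m.params())
        return out

    def buffers(self):
        out = []
        for m in self._modules():
            out.extend(m.buffers())
        return out

    # -- forward / backward --------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        """Logits of shape (N, H, W, 1) for channels-last input
        (N, H, W, C); H and W must be multiples of ``downsample_factor``."""
        if x.shape[1] % self.downsample_factor or x.shape[2] % self.downsample_factor:
            raise ValueError(
                f"spatial size {x.shape[1:3]} not divisible by {self.downsample_factor}; "
                "pad the input first"
            )
        x = self.stem.forward(x, training)
        skips = []
        for stage in self.stages:
            for block in stage:
                x = block.forward(x, training)
            skips.append(x)
        for dec, skip in zip(self.decoders, reversed(skips[:-1])):
            x = dec.forward(x, skip, training)
        return self.head.forward(x, training)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dx = self.head.backward(dlogits)
        dskips = [None] * (len(self.stages) - 1)
        for k in range(len(self.decoders) - 1, -1, -1):  # reverse of forward order
            dx, dskip = self.decoders[k].backward(dx)
            dskips[len(self.stages) - 2 - k] = dskip
        for i in reversed(range(len(self.stages))):
            if i < len(self.stages) - 1:
                dx = dx + dskips[i]
            for block in reversed(self.stages[i]):
                dx = block.backward(dx)
        return self.stem.backward(dx)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid probability maps (N, H, W, 1) in evaluation mode."""
        return sigmoid(self.forward(x, training=False))

    # -- checkpointing -------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.params()] + list(self.buffers())

    def save(self, path) -> None:
        np.savez(path, **{f"arr_{i}": a for i, a in enumerate(self.state_arrays())})

    def load(self, path) -> None:
        with np.load(path) as z:
            arrays = [z[f"arr_{i}"] for i in range(len(z.files))]
        targets = self.state_arrays()
        if len(arrays) != len(targets):
            raise ValueError("checkpoint does not match this architecture")
        for dst, src in zip(targets, arrays):
            if dst.shape != src.shape:
                raise ValueError("checkpoint does not match this architecture")
            dst[...] = src

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.params(), lr=lr)
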