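"""Lightweight watershed-supervised encoder-decoder architecture.

A 4-stage U-Net-style network: each encoder stage is a residual DoubleConv
(two 3x3 same-padded convolutions with ReLU, stage-specific dropout between
them, and an identity shortcut around the second convolution, H(x) =
f(wx + b) + x) followed by 2x2 max pooling; the bottleneck is a plain
DoubleConv at the smallest resolution; each decoder stage upsamples with a
learnable 2x2 stride-2 transposed convolution, concatenates the matching
encoder output, and refines with conv -> ReLU -> dropout -> conv -> ReLU;
a 1x1 convolution plus per-pixel softmax produces the class probabilities.

Default widths 8/16/32/64 with a 128-channel bottleneck give 485,826
trainable parameters with a 2-class head (485,835 with the 3-class head
used for background/nucleus/edge targets).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .nn import BatchNorm2d, Conv2d, ConvTranspose2d, Dropout, MaxPool2x2, ReLU

__all__ = [
    "NetworkConfig", "LayerSpec", "SegmentationNet", "build_layer_specs",
    "count_parameters", "softmax_channels",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``dropout_rates`` holds one rate per encoder stage, strictly increasing
    with depth; the decoder reuses them mirrored (deepest stage first).
    ``use_batch_norm`` inserts BatchNorm2d after every convolution; it is
    off by default because its trainable scale/shift terms change the
    parameter total.
    """

    in_channels: int = 3
    base_width: int = 8
    depth: int = 4
    bottleneck_width: int = 128
    num_classes: int = 3
    dropout_rates: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4)
    transpose_kernel: int = 2
    use_batch_norm: bool = False

    def __post_init__(self) -> None:
        if len(self.dropout_rates) != self.depth:
            raise ValueError("need one dropout rate per encoder stage")
        rates = self.dropout_rates
        if any(not 0.0 <= r < 1.0 for r in rates):
            raise ValueError("dropout rates must lie in [0,1)")
        if any(b <= a for a, b in zip(rates, rates[1:])):
            raise ValueError("dropout rates must be strictly increasing")
        if self.bottleneck_width != self.base_width * 2 ** self.depth:
            raise ValueError(
                f"bottleneck_width must be base_width * 2**depth = "
                f"{self.base_width * 2 ** self.depth}, got {self.bottleneck_width}"
            )
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")

    @property
    def encoder_widths(self) -> tuple[int, ...]:
        return tuple(self.base_width * 2 ** s for s in range(self.depth))


@dataclass(frozen=True)
class LayerSpec:
    """A layer description sufficient for exact parameter counting."""

    kind: str  # conv3x3 | conv1x1 | transpose2x2 | maxpool2x2 | dropout | concat | add | softmax | batch_norm
    in_channels: int = 0
    out_channels: int = 0
    has_bias: bool = False

    @property
    def n_parameters(self) -> int:
        if self.kind == "conv3x3":
            n = 9 * self.in_channels * self.out_channels
        elif self.kind == "conv1x1":
            n = self.in_channels * self.out_channels
        elif self.kind == "transpose2x2":
            n = 4 * self.in_channels * self.out_channels
        elif self.kind == "batch_norm":
            return 2 * self.out_channels
        else:
            return 0
        return n + (self.out_channels if self.has_bias else 0)


def build_layer_specs(config: NetworkConfig) -> list[LayerSpec]:
    """Ordered layer descriptions for the configured architecture."""
    specs: list[LayerSpec] = []

    def conv(kind, cin, cout):
        specs.append(LayerSpec(kind, cin, cout, has_bias=True))
        if config.use_batch_norm:
            specs.append(LayerSpec("batch_norm", cout, cout))

    cin = config.in_channels
    for width in config.encoder_widths:
        conv("conv3x3", cin, width)
        specs.append(LayerSpec("dropout"))
        conv("conv3x3", width, width)
        specs.append(LayerSpec("add"))  # identity shortcut, no parameters
        specs.append(LayerSpec("maxpool2x2"))
        cin = width
    conv("conv3x3", cin, config.bottleneck_width)
    specs.append(LayerSpec("dropout"))
    conv("conv3x3", config.bottleneck_width, config.bottleneck_width)
    cin = config.bottleneck_width
    for width in reversed(config.encoder_widths):
        specs.append(LayerSpec("transpose2x2", cin, width, has_bias=True))
        specs.append(LayerSpec("concat"))
        conv("conv3x3", 2 * width, width)
        specs.append(LayerSpec("dropout"))
        conv("conv3x3", width, width)
        cin = width
    specs.append(LayerSpec("conv1x1", cin, config.num_classes, has_bias=True))
    specs.append(LayerSpec("softmax"))
    return specs


def count_parameters(specs: list[LayerSpec]) -> int:
    """Total trainable parameters of an ordered layer list."""
    return sum(s.n_parameters for s in specs)


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Per-pixel softmax over the channel axis of an (N, C, H, W) array."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _ConvUnit:
    """conv [+ batch norm] + ReLU, the repeated primitive of every block."""

    def __init__(self, cin, cout, kernel, use_bn, rng, dtype):
        self.conv = Conv2d(cin, cout, kernel, bias=True, rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(cout, dtype=dtype) if use_bn else None
        self.relu = ReLU()

    def forward(self, x, training, rng):
        y = self.conv.forward(x, training, rng)
        if self.bn is not None:
            y = self.bn.forward(y, training, rng)
        return self.relu.forward(y, training, rng)

    def backward(self, dout):
        d = self.relu.backward(dout)
        if self.bn is not None:
            d = self.bn.backward(d)
        return self.conv.backward(d)

    def layers(self):
        return [self.conv] + ([self.bn] if self.bn is not None else [])


class _EncoderBlock:
    """Residual DoubleConv: z = ReLU(conv2(y)) + y, y = drop(ReLU(conv1(x)))."""

    def __init__(self, cin, cout, rate, use_bn, rng, dtype):
        self.unit1 = _ConvUnit(cin, cout, 3, use_bn, rng, dtype)
        self.drop = Dropout(rate)
        self.unit2 = _ConvUnit(cout, cout, 3, use_bn, rng, dtype)

    def forward(self, x, training, rng):
        y = self.drop.forward(self.unit1.forward(x, training, rng), training, rng)
        return self.unit2.forward(y, training, rng) + y

    def backward(self, dout):
        dy = self.unit2.backward(dout) + dout  # shortcut adds dout to dy
        return self.unit1.backward(self.drop.backward(dy))

    def layers(self):
        return self.unit1.layers() + self.unit2.layers()


class _Bottleneck:
    """Plain DoubleConv (no shortcut): c5 = ReLU(W2 * D(ReLU(W1*x+b1)) + b2)."""

    def __init__(self, cin, cout, rate, use_bn, rng, dtype):
        self.unit1 = _ConvUnit(cin, cout, 3, use_bn, rng, dtype)
        self.drop = Dropout(rate)
        self.unit2 = _ConvUnit(cout, cout, 3, use_bn, rng, dtype)

    def forward(self, x, training, rng):
        y = self.drop.forward(self.unit1.forward(x, training, rng), training, rng)
        return self.unit2.forward(y, training, rng)

    def backward(self, dout):
        return self.unit1.backward(self.drop.backward(self.unit2.backward(dout)))

    def layers(self):
        return self.unit1.layers() + self.unit2.layers()


class _DecoderBlock:
    """Transpose upsampling, skip concatenation, conv/dropout/conv refinement."""

    def __init__(self, cin, cout, rate, use_bn, rng, dtype):
        self.up = ConvTranspose2d(cin, cout, 2, bias=True, rng=rng, dtype=dtype)
        self.up_relu = ReLU()
        self.unit1 = _ConvUnit(2 * cout, cout, 3, use_bn, rng, dtype)
        self.drop = Dropout(rate)
        self.unit2 = _ConvUnit(cout, cout, 3, use_bn, rng, dtype)
        self.cout = cout

    def forward(self, z_prev, skip, training, rng):
        up = self.up_relu.forward(self.up.forward(z_prev, training, rng), training, rng)
        cat = np.concatenate([up, skip], axis=1)
        y = self.drop.forward(self.unit1.forward(cat, training, rng), training, rng)
        return self.unit2.forward(y, training, rng)

    def backward(self, dout):
        dcat = self.unit1.backward(self.drop.backward(self.unit2.backward(dout)))
        dup, dskip = dcat[:, :self.cout], dcat[:, self.cout:]
        dz = self.up.backward(self.up_relu.backward(dup))
        return dz, dskip

    def layers(self):
        return [self.up] + self.unit1.layers() + self.unit2.layers()


class SegmentationNet:
    """Executable encoder-decoder with exact parameter accounting.

    ``forward`` returns per-pixel class probabilities; ``forward_logits`` /
    ``backward`` expose the pre-softmax interface the training loop uses so
    the loss gradient can be injected directly at the logits.
    """

    def __init__(self, config: NetworkConfig = NetworkConfig(), seed: int = 0,
                 dtype=np.float64):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        use_bn = config.use_batch_norm
        self.encoder: list[_EncoderBlock] = []
        self.pools: list[MaxPool2x2] = []
        cin = config.in_channels
        for width, rate in zip(config.encoder_widths, config.dropout_rates):
            self.encoder.append(_EncoderBlock(cin, width, rate, use_bn, rng, dtype))
            self.pools.append(MaxPool2x2())
            cin = width
        self.bottleneck = _Bottleneck(cin, config.bottleneck_width,
                                      config.dropout_rates[-1], use_bn, rng, dtype)
        self.decoder: list[_DecoderBlock] = []
        cin = config.bottleneck_width
        for width, rate in zip(reversed(config.encoder_widths),
                               reversed(config.dropout_rates)):
            self.decoder.append(_DecoderBlock(cin, width, rate, use_bn, rng, dtype))
            cin = width
        self.head = Conv2d(cin, config.num_classes, kernel=1, bias=True,
                           rng=rng, dtype=dtype)
        # Zero-initialized head: the untrained network outputs the uniform
        # distribution, avoiding saturated softmax logits at the start.
        self.head.params["W"][:] = 0.0

    # -- execution ---------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected (N,{self.config.in_channels},H,W), got {x.shape}")
        factor = 2 ** self.config.depth
        if x.shape[2] % factor or x.shape[3] % factor:
            raise ValueError(
                f"spatial dims must be divisible by {factor}, got {x.shape[2:]}"
            )
        return x

    def forward_logits(self, x: np.ndarray, training: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        x = self._check_input(x)
        skips = []
        for block, pool in zip(self.encoder, self.pools):
            s = block.forward(x, training, rng)
            skips.append(s)
            x = pool.forward(s, training, rng)
        x = self.bottleneck.forward(x, training, rng)
        for block, skip in zip(self.decoder, reversed(skips)):
            x = block.forward(x, skip, training, rng)
        return self.head.forward(x, training, rng)

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Per-pixel class probabilities, (N, num_classes, H, W)."""
        return softmax_channels(self.forward_logits(x, training, rng))

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from a logits-space gradient."""
        d = self.head.backward(dlogits)
        dskips = []
        for block in reversed(self.decoder):
            d, dskip = block.backward(d)
            dskips.append(dskip)
        d = self.bottleneck.backward(d)
        # dskips were collected shallowest-first; encoder unwinds deepest-first.
        for block, pool, dskip in zip(reversed(self.encoder), reversed(self.pools),
                                      reversed(dskips)):
            d = block.backward(pool.backward(d) + dskip)

    # -- parameter access --------------------------------------------------

    def _blocks(self):
        yield from self.encoder
        yield self.bottleneck
        yield from self.decoder

    def layers(self):
        out = []
        for block in self._blocks():
            out.extend(block.layers())
        out.append(self.head)
        return out

    def param_items(self):
        """Yield (unique_key, name, layer) for every trainable array."""
        for i, layer in enumerate(self.layers()):
            for name in layer.params:
                yield f"layer{i}.{name}", name, layer

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for _, name, layer in self.param_items())

    def layer_specs(self) -> list[LayerSpec]:
        return build_layer_specs(self.config)

    def get_weights(self) -> list[np.ndarray]:
        return [copy.deepcopy(layer.params[name]) for _, name, layer in self.param_items()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        items = list(self.param_items())
        if len(weights) != len(items):
            raise ValueError("weight list does not match architecture")
        for (_, name, layer), w in zip(items, weights):
            if layer.params[name].shape != w.shape:
                raise ValueError("weight shape mismatch")
            layer.params[name] = w.astype(self.dtype).copy()

    def save(self, path) -> None:
        """Single-file checkpoint: architecture config + flat weight arrays."""
        import dataclasses as _dc

        arrays = {f"w{i}": w for i, w in enumerate(self.get_weights())}
        meta = _dc.asdict(self.config)
        meta["dropout_rates"] = list(meta["dropout_rates"])
        np.savez(path, __config__=np.array([repr(meta)]), **arrays)

    @classmethod
    def load(cls, path, dtype=np.float64) -> "SegmentationNet":
        import ast

        data = np.load(path, allow_pickle=False)
        meta = ast.literal_eval(str(data["__config__"][0]))
        meta["dropout_rates"] = tuple(meta["dropout_rates"])
        net = cls(NetworkConfig(**meta), dtype=dtype)
        weights = [data[f"w{i}"] for i in range(sum(1 for _ in net.param_items()))]
        net.set_weights(weights)
        return net
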