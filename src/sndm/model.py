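"""Two-level nested U-shaped density-map network with a self-normalization head.

The trunk is a U-shape of residual U-blocks (RSU): each top-level encoder or
decoder block is itself a small U-Net with a residual connection.  Every
decoder block - and the deepest encoder block - emits a side logit map; the
side maps are upsampled to the output resolution, concatenated and fused by a
1x1 convolution into the final logit map S_0.  Probability maps are
P_i = sigmoid(beta * S_i).

In `dm` mode beta is fixed at exactly 1.  In `sndm` mode a bypass head reads
the deepest encoder features (global average pool -> two dense layers) and
predicts a per-image beta through a bounded activation lambda*sigmoid (or
ReLU), letting the network rescale the normalisation of its own output maps.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import Conv2d, ConvRelu, Linear, Module, DTYPE

__all__ = ["ModelConfig", "SideLogits", "BetaValue", "DensityOutputs",
           "DensityMapNet", "build_model", "forward", "apply_normalization",
           "beta_activation", "output_shape", "save_checkpoint",
           "load_checkpoint"]

DEFAULT_LAMBDA = 1.5


@dataclass
class ModelConfig:
    """Architecture knobs; `full_scale` mirrors the 11-block, 6-side layout."""

    mode: str = "sndm"                     # "dm" | "sndm"
    input_size: int = 96
    n_stages: int = 3                      # top-level encoder stages
    base_channels: int = 8
    rsu_depths: list[int] | None = None    # inner-U levels per encoder stage
    dropout_rate: float = 0.1
    beta_activation: str = "scaled_sigmoid"  # or "relu"
    lambda_: float = DEFAULT_LAMBDA
    output_stride: int = 1                 # output map = input / stride
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("dm", "sndm"):
            raise ValueError("mode must be 'dm' or 'sndm'")
        if self.n_stages < 2:
            raise ValueError("n_stages must be >= 2")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0,1)")
        if self.beta_activation not in ("scaled_sigmoid", "relu"):
            raise ValueError("beta_activation must be 'scaled_sigmoid' or 'relu'")
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        if self.output_stride < 1 or self.output_stride & (self.output_stride - 1):
            raise ValueError("output_stride must be a power of two")
        if self.input_size % (2 ** (self.n_stages - 1)):
            raise ValueError(
                f"input_size {self.input_size} not divisible by "
                f"2^(n_stages-1) = {2 ** (self.n_stages - 1)}; resize the "
                "input (or pad it) to a multiple of that stride")
        if self.rsu_depths is None:
            self.rsu_depths = ([2] * (self.n_stages - 1)) + [1]
        if len(self.rsu_depths) != self.n_stages:
            raise ValueError("rsu_depths must have one entry per stage")

    @property
    def n_blocks(self) -> int:
        return 2 * self.n_stages - 1

    @property
    def n_side_outputs(self) -> int:
        return self.n_stages

    @classmethod
    def miniature(cls, mode: str = "sndm", **kw) -> "ModelConfig":
        return cls(mode=mode, **kw)

    @classmethod
    def full_scale(cls, mode: str = "sndm", **kw) -> "ModelConfig":
        """Eleven blocks, six side outputs, output side = input/4."""
        kw.setdefault("input_size", 4032)
        kw.setdefault("n_stages", 6)
        kw.setdefault("base_channels", 64)
        kw.setdefault("rsu_depths", [7, 6, 5, 4, 4, 4])
        kw.setdefault("output_stride", 4)
        return cls(mode=mode, **kw)


def output_shape(config: ModelConfig,
                 input_hw: tuple[int, int] | None = None) -> tuple[int, int]:
    """Spatial size of the output maps for a given input size."""
    if input_hw is None:
        input_hw = (config.input_size, config.input_size)
    return (input_hw[0] // config.output_stride,
            input_hw[1] // config.output_stride)


@dataclass
class BetaValue:
    """Per-image normalisation parameter and the bound of its activation."""

    beta: float
    lambda_: float = DEFAULT_LAMBDA


@dataclass
class SideLogits:
    """Pre-sigmoid side maps S_1..S_K (upsampled) and the fused map S_0."""

    maps: list[np.ndarray]
    fused: np.ndarray


@dataclass
class DensityOutputs:
    """Probability maps P_0..P_K, the beta in effect, and the count (sum of P_0)."""

    maps: list[np.ndarray]          # [P_0, P_1, ..., P_K]
    logits: SideLogits
    beta: BetaValue
    predicted_count: float

    @property
    def P0(self) -> np.ndarray:
        return self.maps[0]


# ------------------------------------------------------------------- blocks

class RSU(Module):
    """Residual U-block: inner encoder-decoder of `depth` levels + skip."""

    def __init__(self, depth: int, c_in: int, c_mid: int, c_out: int,
                 rng: np.random.Generator):
        self.depth = depth
        self.conv_in = ConvRelu(c_in, c_out, 3, rng)
        self.enc = [ConvRelu(c_out if l == 0 else c_mid, c_mid, 3, rng)
                    for l in range(depth)]
        self.bottom = ConvRelu(c_mid, c_mid, 3, rng, dilation=2)
        self.dec = [ConvRelu(2 * c_mid, c_out if l == 0 else c_mid, 3, rng)
                    for l in range(depth)]

    def __call__(self, x: Tensor, rate: float, rng, training: bool) -> Tensor:
        xin = self.conv_in(x)
        e = [self.enc[0](xin)]
        for l in range(1, self.depth):
            e.append(self.enc[l](ag.maxpool2(e[-1])))
        h = self.bottom(e[-1])
        h = ag.dropout_channels(h, rate, rng, training)   # inner-encoder end
        for l in range(self.depth - 1, 0, -1):
            h = ag.upsample2x(self.dec[l](ag.concat([h, e[l]])))
        h = self.dec[0](ag.concat([h, e[0]]))
        h = ag.dropout_channels(h, rate, rng, training)   # inner-decoder end
        return ag.add(xin, h)


class BetaHead(Module):
    """Bypass head on the deepest encoder block: GAP -> FC(32) -> FC(1) -> act.

    The final bias is initialised so that an untrained head proposes beta = 1
    (no rescaling); weights are small so early training stays near that point.
    """

    HIDDEN = 32

    def __init__(self, c_in: int, activation: str, lambda_: float,
                 rng: np.random.Generator):
        self.activation = activation
        self.lambda_ = lambda_
        self.fc1 = Linear(c_in, self.HIDDEN, rng)
        self.fc2 = Linear(self.HIDDEN, 1, rng)
        self.fc2.w.data = (self.fc2.w.data * 0.01).astype(DTYPE)
        if activation == "scaled_sigmoid":
            # lambda*sigmoid(b) = 1  =>  b = -log(lambda - 1)
            b0 = -math.log(lambda_ - 1.0) if lambda_ > 1.0 else 0.0
        else:
            b0 = 1.0
        self.fc2.b.data = np.full(1, b0, dtype=DTYPE)

    def __call__(self, features: Tensor) -> Tensor:
        h = ag.relu(self.fc1(ag.global_avg_pool(features)))
        z = self.fc2(h)                                   # (N, 1)
        if self.activation == "scaled_sigmoid":
            return ag.mul(Tensor(np.asarray(self.lambda_, dtype=z.dtype)),
                          ag.sigmoid(z))
        return ag.relu(z)


# -------------------------------------------------------------------- model

def _stage_channels(config: ModelConfig) -> list[int]:
    cap = min(3, config.n_stages - 2) if config.n_stages > 2 else 1
    return [config.base_channels * 2 ** min(i, cap)
            for i in range(config.n_stages)]


class DensityMapNet(Module):
    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        s = config.n_stages
        ch = _stage_channels(config)
        mid = [max(c // 2, 4) for c in ch]

        self.enc_blocks = []
        c_prev = 3
        for i in range(s):
            self.enc_blocks.append(RSU(config.rsu_depths[i], c_prev, mid[i],
                                       ch[i], rng))
            c_prev = ch[i]

        self.dec_blocks = []
        c_prev = ch[s - 1]
        for i in range(s - 2, -1, -1):
            self.dec_blocks.append(RSU(config.rsu_depths[i], c_prev + ch[i],
                                       mid[i], ch[i], rng))
            c_prev = ch[i]
        # side sources, shallowest decoder first, bottleneck encoder last
        side_channels = ch[: s - 1] + [ch[s - 1]]
        self.side_convs = [Conv2d(c, 1, 1, rng) for c in side_channels]
        self.fuse_conv = Conv2d(s, 1, 1, rng)
        self.head = (BetaHead(ch[s - 1], config.beta_activation,
                              config.lambda_, rng)
                     if config.mode == "sndm" else None)
        #: when set to a float, the head is bypassed and beta is forced
        self.beta_override: float | None = None

    @property
    def n_blocks(self) -> int:
        return len(self.enc_blocks) + len(self.dec_blocks)

    # ---------------------------------------------------------------- graph

    def _forward_graph(self, x: Tensor, training: bool = False,
                       dropout_rng: np.random.Generator | None = None,
                       ) -> tuple[list[Tensor], Tensor]:
        """Return ([S_0, S_1, ..., S_K] upsampled logit maps, beta (N,1))."""
        cfg = self.config
        rate = cfg.dropout_rate
        rng = dropout_rng if dropout_rng is not None else np.random.default_rng()
        for _ in range(int(math.log2(cfg.output_stride))):
            x = ag.avgpool2(x)

        h = x
        enc_feats = []
        for i, blk in enumerate(self.enc_blocks):
            if i > 0:
                h = ag.maxpool2(h)
            h = blk(h, rate, rng, training)
            enc_feats.append(h)

        bottleneck = enc_feats[-1]
        dec_feats = []
        h = bottleneck
        for j, blk in enumerate(self.dec_blocks):
            i = cfg.n_stages - 2 - j
            h = blk(ag.concat([ag.upsample2x(h), enc_feats[i]]),
                    rate, rng, training)
            dec_feats.append(h)

        # S_1 shallowest decoder ... S_{K-1} deepest decoder, S_K bottleneck
        sources = list(reversed(dec_feats)) + [bottleneck]
        sides = []
        for k, src in enumerate(sources):
            sm = self.side_convs[k](src)
            for _ in range(k):       # source k lives at output_res / 2^k
                sm = ag.upsample2x(sm)
            sides.append(sm)
        fused = self.fuse_conv(ag.concat(sides))

        N = x.data.shape[0]
        if self.beta_override is not None:
            beta = Tensor(np.full((N, 1), self.beta_override, dtype=x.data.dtype))
        elif self.head is None:
            beta = Tensor(np.ones((N, 1), dtype=x.data.dtype))
        else:
            beta = self.head(bottleneck)
        return [fused] + sides, beta

    def probability_maps(self, S: list[Tensor], beta: Tensor) -> list[Tensor]:
        """P_i = sigmoid(beta * S_i); beta exactly 1 leaves logits untouched."""
        b4 = ag.reshape(beta, (beta.data.shape[0], 1, 1, 1))
        return [ag.sigmoid(ag.mul(b4, s)) for s in S]

    def beta_head(self, bottleneck_features: np.ndarray | Tensor) -> BetaValue:
        """Evaluate the bypass head on (N,C,h,w) features of the deepest block."""
        if self.head is None:
            return BetaValue(beta=1.0, lambda_=self.config.lambda_)
        t = (bottleneck_features if isinstance(bottleneck_features, Tensor)
             else Tensor(np.asarray(bottleneck_features, dtype=DTYPE)))
        out = self.head(t)
        return BetaValue(beta=float(out.data.reshape(-1)[0]),
                         lambda_=self.config.lambda_)


# ---------------------------------------------------------------- functions

def build_model(config: ModelConfig) -> DensityMapNet:
    """Construct the network with deterministic, seed-driven initialisation."""
    return DensityMapNet(config)


def _as_batch(image: np.ndarray, input_size: int) -> np.ndarray:
    img = np.asarray(image, dtype=DTYPE)
    if img.shape != (input_size, input_size, 3):
        raise ValueError(f"expected image of shape ({input_size}, {input_size}, 3), "
                         f"got {img.shape}")
    return img[None]


def forward(model: DensityMapNet, image: np.ndarray) -> DensityOutputs:
    """Deterministic (dropout-free) inference on one H x W x 3 image in [0,1]."""
    cfg = model.config
    x = Tensor(_as_batch(image, cfg.input_size))
    S, beta = model._forward_graph(x, training=False)
    P = model.probability_maps(S, beta)
    maps = [p.data[0, :, :, 0].astype(np.float64) for p in P]
    logits = SideLogits(maps=[s.data[0, :, :, 0].astype(np.float64) for s in S[1:]],
                        fused=S[0].data[0, :, :, 0].astype(np.float64))
    b = float(beta.data.reshape(-1)[0])
    return DensityOutputs(maps=maps, logits=logits,
                          beta=BetaValue(beta=b, lambda_=cfg.lambda_),
                          predicted_count=float(maps[0].sum()))


def apply_normalization(S: np.ndarray, beta: float) -> np.ndarray:
    """Elementwise sigmoid(beta * S); beta = 1 is the plain sigmoid."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    z = beta * np.asarray(S, dtype=np.float64)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def beta_activation(pre_activation: float, kind: str = "scaled_sigmoid",
                    lambda_: float = DEFAULT_LAMBDA) -> float:
    """The head's output activation: lambda*sigmoid(z), or ReLU(z)."""
    if kind == "scaled_sigmoid":
        return float(lambda_ / (1.0 + math.exp(-pre_activation)))
    if kind == "relu":
        return float(max(pre_activation, 0.0))
    raise ValueError("kind must be 'scaled_sigmoid' or 'relu'")


# ------------------------------------------------------------------- saving

def save_checkpoint(model: DensityMapNet, path: str | Path) -> None:
    cfg = json.dumps(dataclasses.asdict(model.config))
    np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path: str | Path) -> DensityMapNet:
    with np.load(path) as z:
        cfg = json.loads(bytes(z["__config__"]).decode())
        model = DensityMapNet(ModelConfig(**cfg))
        model.load_state_dict({k: z[k] for k in z.files if k != "__config__"})
    return model
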