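"""The SE-gated inception encoder-decoder for multi-label tooth segmentation.

Architecture, end to end (reference spatial sizes for a 256 x 512 input):

* **Encoder** — five stages, each halving the spatial size, yielding taps
  D1..D5 at strides 2, 4, 8, 16, 32 with depths 64, 192, 288, 768, 2048
  (an InceptionV3-shaped stack; a ``tiny`` backbone keeps the identical
  stride contract at small depths for fast CPU experiments).
* **Feature integration** — pointwise convolutions equalize all taps to a
  common depth (128 reference), then a top-down pyramid adds each upsampled
  coarser map into the next finer one: F5 = E5, F_{i-1} = Up2(F_i) + E_{i-1}.
* **SE inception gates** — each F_i passes a three-branch inception block
  (5x5 conv, double 3x3 conv, max-pool + pointwise), every branch rescaled
  elementwise by a squeeze-and-excitation gate: two stacked pointwise
  convolutions (squeeze to c/2, expand back to c) produce a weight map whose
  sigmoid multiplies the branch.  Note this gate is purely convolutional —
  there is no global average pooling stage, so the weights vary per pixel.
* **Fusion + head** — M1..M4 are upsampled to the finest decoder size,
  concatenated to depth 4 x 3 x branch_width (768 reference), passed through
  Conv-BN-ReLU, upsampled to full resolution and projected to the output
  channels: 32 per-tooth planes under a sigmoid (multi-label, overlap aware)
  or 33 classes (32 teeth + background) under a per-pixel softmax.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .synthetic import ToothMaskStack
from .fdi import build_fdi_label_map

__all__ = [
    "EncoderConfig", "SEIBConfig", "NetworkConfig",
    "FeaturePyramid", "DecoderFeatures", "PredictionStack",
    "SEIBEDNetwork", "threshold_predictions", "softmax_to_binary",
    "REFERENCE_TAP_DEPTHS", "TINY_TAP_DEPTHS",
]

REFERENCE_TAP_DEPTHS = (64, 192, 288, 768, 2048)
TINY_TAP_DEPTHS = (8, 16, 24, 32, 48)

_STRIDES = (2, 4, 8, 16, 32)


@dataclass(frozen=True)
class EncoderConfig:
    backbone: str = "inceptionv3"
    tap_depths: tuple[int, ...] = REFERENCE_TAP_DEPTHS
    channels_in: int = 3

    def __post_init__(self) -> None:
        if self.backbone not in ("inceptionv3", "tiny"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if len(self.tap_depths) != 5 or any(d <= 0 for d in self.tap_depths):
            raise ValueError("tap_depths must be 5 positive integers")


@dataclass(frozen=True)
class SEIBConfig:
    """Inception-branch width and SE bottleneck. The gate's expansion width
    always equals the branch depth; ``branch_width`` must be even so the
    squeeze stage (half width) is integral."""

    branch_width: int = 64
    pool_kernel: int = 3

    def __post_init__(self) -> None:
        if self.branch_width <= 0 or self.branch_width % 2:
            raise ValueError("branch_width must be positive and even")


@dataclass(frozen=True)
class NetworkConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    seib: SEIBConfig = field(default_factory=SEIBConfig)
    fib_depth: int = 128
    head_width: int = 128
    activation: str = "sigmoid"          # sigmoid (32ch) | softmax (33ch incl background)
    upsample: str = "nearest"            # nearest | bilinear
    branch_batch_norm: bool = True
    threshold: float = 0.5
    head_bias_init: float = -3.0         # foreground-prior logit for tooth channels

    def __post_init__(self) -> None:
        if self.activation not in ("sigmoid", "softmax"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.upsample not in ("nearest", "bilinear"):
            raise ValueError(f"unknown upsample mode {self.upsample!r}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def out_channels(self) -> int:
        return 32 if self.activation == "sigmoid" else 33

    @classmethod
    def tiny(cls, activation: str = "sigmoid", **kw) -> "NetworkConfig":
        """Desk-scale preset: same stride/shape contracts, small depths."""
        return cls(
            encoder=EncoderConfig(backbone="tiny", tap_depths=TINY_TAP_DEPTHS),
            seib=SEIBConfig(branch_width=8),
            fib_depth=32,
            head_width=32,
            activation=activation,
            **kw,
        )


@dataclass
class FeaturePyramid:
    """Encoder taps D1..D5 (batch, H, W, depth) at strides 2..32."""

    D1: Tensor
    D2: Tensor
    D3: Tensor
    D4: Tensor
    D5: Tensor

    def taps(self) -> list[Tensor]:
        return [self.D1, self.D2, self.D3, self.D4, self.D5]

    def shapes(self) -> list[tuple[int, int, int]]:
        return [tuple(t.data.shape[1:]) for t in self.taps()]


@dataclass
class DecoderFeatures:
    """Decoder maps: depth-equalized taps E, pyramid sums F, gated blocks M,
    and the fused map at the finest decoder resolution."""

    E: list[Tensor]
    F: list[Tensor]
    M: list[Tensor]
    F_final: Tensor


@dataclass
class PredictionStack:
    """Segmentation output: raw logits and activated probabilities.

    Sigmoid: 32 independent per-tooth planes, per-pixel channel sums free to
    exceed 1 (that is the point — overlapping teeth).  Softmax: 33 channels
    (32 teeth plus background at index 32) normalized per pixel.
    """

    logits: np.ndarray
    probs: np.ndarray
    activation: str

    @property
    def n_channels(self) -> int:
        return self.probs.shape[-1]


class _SEGate:
    """Squeeze-and-excitation gate: WK = sigmoid(PC_c(PC_{c/2}(K))) * K.

    Implemented literally as two stacked pointwise convolutions with no
    global pooling, so the gate is spatially varying.  ``c`` is tied to the
    input depth (the gated output must match K's shape).
    """

    def __init__(self, channels: int, rng: np.random.Generator) -> None:
        if channels % 2:
            raise ValueError("SE gate channel count must be even")
        self.squeeze = nn.Conv2d(channels, channels // 2, kernel=1, rng=rng)
        self.expand = nn.Conv2d(channels // 2, channels, kernel=1, rng=rng)

    def __call__(self, K: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """Returns (cf, scf, WK): pre-activation weights, sigmoid weights,
        and the gated feature map."""
        cf = self.expand(self.squeeze(K))
        scf = nn.sigmoid(cf)
        WK = nn.mul(scf, K)
        return cf, scf, WK

    def params(self) -> list[Tensor]:
        return self.squeeze.params() + self.expand.params()


class _SEInceptionBlock:
    """Three-branch inception block with SE gating on every branch.

    level1 = Conv5x5(PC(F)); level2 = Conv3x3(Conv3x3(PC(F)));
    level3 = PC(MaxPool3x3(F)); output = depth-concat of the gated branches.
    """

    def __init__(self, c_in: int, cfg: SEIBConfig, rng: np.random.Generator,
                 batch_norm: bool = True) -> None:
        bw = cfg.branch_width
        self.pc1 = nn.Conv2d(c_in, bw, kernel=1, rng=rng)
        self.conv5 = nn.ConvBNRelu(bw, bw, kernel=5, rng=rng, batch_norm=batch_norm)
        self.pc2 = nn.Conv2d(c_in, bw, kernel=1, rng=rng)
        self.conv3a = nn.ConvBNRelu(bw, bw, kernel=3, rng=rng, batch_norm=batch_norm)
        self.conv3b = nn.ConvBNRelu(bw, bw, kernel=3, rng=rng, batch_norm=batch_norm)
        self.pc3 = nn.Conv2d(c_in, bw, kernel=1, rng=rng)
        self.gates = [_SEGate(bw, rng) for _ in range(3)]
        self.pool_kernel = cfg.pool_kernel

    def __call__(self, F: Tensor, training: bool = False) -> Tensor:
        k1 = self.conv5(self.pc1(F), training)
        k2 = self.conv3b(self.conv3a(self.pc2(F), training), training)
        k3 = self.pc3(nn.maxpool_same(F, self.pool_kernel))
        gated = [gate(k)[2] for gate, k in zip(self.gates, (k1, k2, k3))]
        return nn.concat(gated, axis=3)

    def params(self) -> list[Tensor]:
        out = self.pc1.params() + self.conv5.params() + self.pc2.params()
        out += self.conv3a.params() + self.conv3b.params() + self.pc3.params()
        for g in self.gates:
            out += g.params()
        return out


class SEIBEDNetwork:
    """Full segmentation network; construct with a config and an init seed."""

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0) -> None:
        self.config = config or NetworkConfig()
        self.seed = int(seed)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xC0DE]))
        enc = self.config.encoder
        depths = enc.tap_depths
        bn = self.config.branch_batch_norm

        # ---- encoder: 5 strided stages (+ pointwise depth expansion) ----
        self._stages = []
        c_prev = enc.channels_in
        for d in depths:
            width = min(d, 512) if enc.backbone == "inceptionv3" else d
            stage = [nn.ConvBNRelu(c_prev, width, kernel=3, stride=2, rng=rng,
                                   batch_norm=bn)]
            if width != d:
                stage.append(nn.ConvBNRelu(width, d, kernel=1, rng=rng,
                                           batch_norm=bn))
            self._stages.append(stage)
            c_prev = d

        # ---- feature integration: depth-equalizing pointwise convs ----
        fd = self.config.fib_depth
        self._reducers = [nn.Conv2d(d, fd, kernel=1, rng=rng) for d in depths]

        # ---- SE inception blocks on F1..F4 ----
        self._seibs = [_SEInceptionBlock(fd, self.config.seib, rng, batch_norm=bn)
                       for _ in range(4)]

        # ---- head ----
        fused_depth = 4 * 3 * self.config.seib.branch_width
        self._head_conv = nn.ConvBNRelu(fused_depth, self.config.head_width,
                                        kernel=3, rng=rng, batch_norm=bn)
        self._head_proj = nn.Conv2d(self.config.head_width,
                                    self.config.out_channels, kernel=1, rng=rng,
                                    bias_init=self.config.head_bias_init)
        if self.config.activation == "softmax":
            # background channel starts near the class prior instead of the
            # tooth-channel prior
            self._head_proj.b.data[32] = 0.0

    # ------------------------------------------------------------------
    def _up(self, x: Tensor, factor: int) -> Tensor:
        if self.config.upsample == "nearest":
            return nn.upsample_nearest(x, factor)
        return nn.upsample_bilinear(x, factor)

    @staticmethod
    def _as_batch(images: np.ndarray) -> np.ndarray:
        arr = np.asarray(images, dtype=np.float32)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError("expected (H, W) or (N, H, W) grayscale input")
        return arr

    def encode(self, images: np.ndarray, training: bool = False) -> FeaturePyramid:
        """Run the encoder; returns taps D1..D5 at strides 2..32.

        Grayscale input is replicated across ``channels_in`` planes.
        """
        arr = self._as_batch(images)
        H, W = arr.shape[1:]
        if H % 32 or W % 32:
            raise ValueError(f"input spatial dims {H}x{W} must be divisible by 32")
        x = Tensor(np.repeat(arr[..., None], self.config.encoder.channels_in, axis=3))
        taps = []
        for stage in self._stages:
            for layer in stage:
                x = layer(x, training)
            taps.append(x)
        return FeaturePyramid(*taps)

    def pointwise_reduce(self, pyramid: FeaturePyramid, training: bool = False) -> list[Tensor]:
        """E_i = PC_fib_depth(D_i): equalize tap depths, spatial unchanged."""
        return [pc(d) for pc, d in zip(self._reducers, pyramid.taps())]

    def integrate_features(self, E: list[Tensor]) -> list[Tensor]:
        """Top-down pyramid: F5 = E5; F_{i-1} = Up2(F_i) + E_{i-1}.

        Returns [F1, F2, F3, F4, F5] (F5 kept for completeness)."""
        F = [None] * 5
        F[4] = E[4]
        for i in range(4, 0, -1):
            F[i - 1] = nn.add(self._up(F[i], 2), E[i - 1])
        return F

    def se_inception(self, F: list[Tensor], training: bool = False) -> list[Tensor]:
        """Gated inception blocks: M_i = SE-IB(F_i) for i = 1..4."""
        return [blk(f, training) for blk, f in zip(self._seibs, F[:4])]

    def fuse_decoder(self, M: list[Tensor]) -> Tensor:
        """Concat[M1, Up2(M2), Up4(M3), Up8(M4)] at the finest decoder size."""
        pieces = [M[0]] + [self._up(m, 2 ** i) for i, m in enumerate(M[1:], start=1)]
        ref = pieces[0].data.shape[1:3]
        for p in pieces:
            if p.data.shape[1:3] != ref:
                raise ValueError("decoder maps do not share spatial dims after upsampling")
        return nn.concat(pieces, axis=3)

    def segmentation_head(self, F_final: Tensor, training: bool = False) -> Tensor:
        """Conv-BN-ReLU, upsample to full resolution, project to channels.

        Returns logits; activation is applied by :meth:`forward`."""
        x = self._head_conv(F_final, training)
        x = self._up(x, 2)
        return self._head_proj(x)

    def forward_tensor(self, images: np.ndarray, training: bool = False,
                       return_features: bool = False):
        pyr = self.encode(images, training)
        E = self.pointwise_reduce(pyr, training)
        F = self.integrate_features(E)
        M = self.se_inception(F, training)
        F_final = self.fuse_decoder(M)
        logits = self.segmentation_head(F_final, training)
        if return_features:
            return logits, pyr, DecoderFeatures(E=E, F=F, M=M, F_final=F_final)
        return logits

    def forward(self, images: np.ndarray, training: bool = False) -> PredictionStack:
        """Full forward pass to a :class:`PredictionStack` of probabilities."""
        logits = self.forward_tensor(images, training)
        z = logits.data
        if self.config.activation == "sigmoid":
            probs = nn.autograd.sigmoid_array(z)
        else:
            probs = nn.softmax(z, axis=-1)
        return PredictionStack(logits=z, probs=probs, activation=self.config.activation)

    def params(self) -> list[Tensor]:
        out = []
        for stage in self._stages:
            for layer in stage:
                out += layer.params()
        for pc in self._reducers:
            out += pc.params()
        for blk in self._seibs:
            out += blk.params()
        out += self._head_conv.params() + self._head_proj.params()
        return out

    # ------------------------------------------------------------------
    # checkpointing: one .npz with the config embedded as JSON
    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        cfg = {
            "format_version": 1,
            "seed": self.seed,
            "encoder": {"backbone": self.config.encoder.backbone,
                        "tap_depths": list(self.config.encoder.tap_depths),
                        "channels_in": self.config.encoder.channels_in},
            "seib": {"branch_width": self.config.seib.branch_width,
                     "pool_kernel": self.config.seib.pool_kernel},
            "fib_depth": self.config.fib_depth,
            "head_width": self.config.head_width,
            "activation": self.config.activation,
            "upsample": self.config.upsample,
            "branch_batch_norm": self.config.branch_batch_norm,
            "threshold": self.config.threshold,
            "head_bias_init": self.config.head_bias_init,
        }
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        np.savez_compressed(path, config=json.dumps(cfg), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SEIBEDNetwork":
        with np.load(path, allow_pickle=False) as z:
            cfg = json.loads(str(z["config"]))
            config = NetworkConfig(
                encoder=EncoderConfig(backbone=cfg["encoder"]["backbone"],
                                      tap_depths=tuple(cfg["encoder"]["tap_depths"]),
                                      channels_in=cfg["encoder"]["channels_in"]),
                seib=SEIBConfig(branch_width=cfg["seib"]["branch_width"],
                                pool_kernel=cfg["seib"]["pool_kernel"]),
                fib_depth=cfg["fib_depth"], head_width=cfg["head_width"],
                activation=cfg["activation"], upsample=cfg["upsample"],
                branch_batch_norm=cfg["branch_batch_norm"],
                threshold=cfg["threshold"], head_bias_init=cfg["head_bias_init"],
            )
            net = cls(config, seed=cfg["seed"])
            for i, p in enumerate(net.params()):
                p.data = z[f"p{i}"].astype(np.float32)
        return net


def threshold_predictions(stack: PredictionStack, t: float = 0.5) -> np.ndarray:
    """Binarize a sigmoid stack channelwise: pixel = 1 iff prob > t.

    Channels are thresholded independently, so multi-label overlap survives.
    Returns (N, H, W, 32) uint8.  A softmax stack has no per-channel
    threshold semantics; convert it with :func:`softmax_to_binary` instead.
    """
    if stack.activation != "sigmoid":
        raise ValueError(
            "threshold_predictions requires a sigmoid stack; use "
            "softmax_to_binary for a softmax stack"
        )
    if not 0.0 <= t < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    return (stack.probs > t).astype(np.uint8)


def softmax_to_binary(stack: PredictionStack) -> np.ndarray:
    """Single-label reduction of a softmax stack to per-tooth planes.

    Each pixel is assigned its argmax class; the background class (index 32)
    produces no foreground.  Returns (N, H, W, 32) uint8 one-hot planes.
    """
    if stack.activation != "softmax":
        raise ValueError("softmax_to_binary requires a softmax stack")
    labels = stack.probs.argmax(axis=-1)
    out = np.zeros(stack.probs.shape[:-1] + (32,), dtype=np.uint8)
    for ch in range(32):
        out[..., ch] = labels == ch
    return out


def masks_to_stack(planes: np.ndarray) -> ToothMaskStack:
    """Wrap raw (H, W, 32) planes with the canonical label map."""
    return ToothMaskStack(planes, build_fdi_label_map())
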