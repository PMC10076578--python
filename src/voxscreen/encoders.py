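"""Speaker-embedding encoders: TDNN x-vector and ResNet34 x-vector.

The TDNN stack splices temporally offset context frames in its first three
layers (contexts {-2..2}, {-2,0,2}, {-3,0,3}) followed by two 1-frame layers,
so one frame after the third delay operation depends on 15 input frames.
Statistics pooling (mean + std over time) converts the variable-length
frame-level output to a fixed vector; the embedding is the output of the
first segment-level affine, taken pre-nonlinearity.

The ResNet34 encoder treats the (F=60) x T feature matrix as a one-channel
image: a 7x7 stride-1 convolution, four residual stages with (3, 4, 6, 3)
basic blocks and (32, 64, 128, 256) channels, stride-2 downsampling at stages
2-4 (ceil mode, 60 -> 30 -> 15 -> 8 along the feature axis), statistics
pooling over time on the channel-by-frequency-collapsed maps, and a segment
affine to the embedding dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from voxscreen.errors import ArgumentError
from voxscreen.nnet import (
    AdamW,
    Affine,
    Conv2D,
    Param,
    ReLU,
    ResBlock,
    SpliceAffine,
    StatsPool,
    softmax_cross_entropy,
)

TDNN_CONTEXTS_DEFAULT = ([-2, -1, 0, 1, 2], [-2, 0, 2], [-3, 0, 3], [0], [0])
TDNN_DIMS_DEFAULT = (512, 512, 512, 512, 1500)
RESNET_BLOCKS = (3, 4, 6, 3)
RESNET_CHANNELS = (32, 64, 128, 256)
RESNET_STRIDES = (1, 2, 2, 2)


@dataclass
class EncoderSpec:
    """Architecture description of one embedding extractor."""

    kind: str  # "tdnn" | "resnet34"
    embedding_dim: int = 256
    feat_dim: int = 60
    # TDNN
    tdnn_contexts: tuple = TDNN_CONTEXTS_DEFAULT
    tdnn_dims: tuple = TDNN_DIMS_DEFAULT
    # ResNet
    resnet_blocks: tuple = RESNET_BLOCKS
    resnet_channels: tuple = RESNET_CHANNELS
    resnet_strides: tuple = RESNET_STRIDES
    first_kernel: int = 7
    kernel: int = 3

    def __post_init__(self) -> None:
        self.kind = self.kind.lower()
        if self.kind not in ("tdnn", "resnet34"):
            raise ArgumentError(f"unknown encoder kind {self.kind!r}")
        if self.embedding_dim < 1:
            raise ArgumentError("embedding_dim must be positive")
        if self.kind == "tdnn":
            if len(self.tdnn_contexts) != len(self.tdnn_dims):
                raise ArgumentError("tdnn_contexts and tdnn_dims must align")
        else:
            if not (len(self.resnet_blocks) == len(self.resnet_channels) == len(self.resnet_strides)):
                raise ArgumentError("resnet blocks/channels/strides must align")

    @classmethod
    def tdnn(cls, embedding_dim: int = 256, feat_dim: int = 60, hidden: int | None = None) -> "EncoderSpec":
        dims = TDNN_DIMS_DEFAULT if hidden is None else (hidden, hidden, hidden, hidden, hidden * 3)
        return cls(kind="tdnn", embedding_dim=embedding_dim, feat_dim=feat_dim, tdnn_dims=dims)

    @classmethod
    def resnet34(cls, embedding_dim: int = 256, feat_dim: int = 60) -> "EncoderSpec":
        return cls(kind="resnet34", embedding_dim=embedding_dim, feat_dim=feat_dim)

    @classmethod
    def tiny_tdnn(cls, embedding_dim: int = 64, feat_dim: int = 60) -> "EncoderSpec":
        """Desk-scale TDNN: same context stack (receptive field 15), thin layers."""
        return cls.tdnn(embedding_dim=embedding_dim, feat_dim=feat_dim, hidden=48)

    @classmethod
    def tiny_resnet(cls, embedding_dim: int = 32, feat_dim: int = 60) -> "EncoderSpec":
        """Desk-scale ResNet: the Table-3 stage layout with 1 block and few channels."""
        return cls(
            kind="resnet34",
            embedding_dim=embedding_dim,
            feat_dim=feat_dim,
            resnet_blocks=(1, 1, 1, 1),
            resnet_channels=(4, 8, 16, 32),
            resnet_strides=RESNET_STRIDES,
        )

    @property
    def receptive_field(self) -> int:
        """Input frames one top frame-level TDNN frame depends on."""
        if self.kind != "tdnn":
            raise ArgumentError("receptive_field is a TDNN notion")
        return sum(max(c) - min(c) for c in self.tdnn_contexts) + 1

    def resnet_shape_trace(self, T: int) -> list[tuple[str, int, int, int]]:
        """(layer name, channels, F, T) after each ResNet stage (ceil-mode)."""
        if self.kind != "resnet34":
            raise ArgumentError("shape trace is a ResNet notion")
        F = self.feat_dim
        trace = [("conv1", self.resnet_channels[0], F, T)]
        for i, (ch, s) in enumerate(zip(self.resnet_channels, self.resnet_strides)):
            F = -(-F // s)
            T = -(-T // s)
            trace.append((f"resblock{i + 1}", ch, F, T))
        return trace

    @property
    def min_frames(self) -> int:
        return self.receptive_field if self.kind == "tdnn" else 8


class TDNNEncoder:
    """Frame-level TDNN stack + stats pooling + segment-level affines."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        self.spec = spec
        self.frame_layers: list = []
        in_dim = spec.feat_dim
        for contexts, dim in zip(spec.tdnn_contexts, spec.tdnn_dims):
            self.frame_layers.append(SpliceAffine(list(contexts), in_dim, dim, rng))
            self.frame_layers.append(ReLU())
            in_dim = dim
        self.pool = StatsPool()
        self.segment1 = Affine(2 * in_dim, spec.embedding_dim, rng)  # embedding tap
        self.seg_relu = ReLU()
        self.segment2 = Affine(spec.embedding_dim, spec.embedding_dim, rng)
        self.seg_relu2 = ReLU()
        self.head: Affine | None = None
        self._head_rng = rng

    def set_head(self, n_speakers: int) -> None:
        self.head = Affine(self.spec.embedding_dim, n_speakers, self._head_rng)

    def _frame_forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.frame_layers:
            x = layer.forward(x)
        return x

    def embed(self, features: np.ndarray) -> np.ndarray:
        """Embedding of one (T, F) utterance: first segment affine output."""
        x = np.asarray(features, dtype=np.float64)[None]
        if x.shape[1] < self.spec.min_frames:
            raise ArgumentError(
                f"need >= {self.spec.min_frames} frames for the TDNN receptive field, got {x.shape[1]}"
            )
        h = self.pool.forward(self._frame_forward(x))
        return self.segment1.forward(h)[0]

    def forward_train(self, x: np.ndarray) -> np.ndarray:
        if self.head is None:
            raise ArgumentError("classification head not initialized; call set_head")
        h = self.pool.forward(self._frame_forward(x))
        h = self.seg_relu.forward(self.segment1.forward(h))
        h = self.seg_relu2.forward(self.segment2.forward(h))
        return self.head.forward(h)

    def backward(self, grad: np.ndarray) -> None:
        g = self.head.backward(grad)
        g = self.segment2.backward(self.seg_relu2.backward(g))
        g = self.segment1.backward(self.seg_relu.backward(g))
        g = self.pool.backward(g)
        for layer in reversed(self.frame_layers):
            g = layer.backward(g)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.frame_layers:
            out += layer.params()
        out += self.segment1.params() + self.segment2.params()
        if self.head is not None:
            out += self.head.params()
        return out


class ResNetEncoder:
    """ResNet34-style encoder over (1, F, T) feature maps."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        self.spec = spec
        self.conv1 = Conv2D(1, spec.resnet_channels[0], spec.first_kernel, 1, rng)
        self.relu1 = ReLU()
        self.blocks: list[ResBlock] = []
        in_ch = spec.resnet_channels[0]
        for n_blocks, ch, stride in zip(spec.resnet_blocks, spec.resnet_channels, spec.resnet_strides):
            for b in range(n_blocks):
                self.blocks.append(ResBlock(in_ch, ch, spec.kernel, stride if b == 0 else 1, rng))
                in_ch = ch
        self.pool = StatsPool()
        F_out = spec.feat_dim
        for s in spec.resnet_strides:
            F_out = -(-F_out // s)
        self.pooled_dim = 2 * in_ch * F_out
        self.segment1 = Affine(self.pooled_dim, spec.embedding_dim, rng)  # embedding tap
        self.seg_relu = ReLU()
        self.head: Affine | None = None
        self._head_rng = rng

    def set_head(self, n_speakers: int) -> None:
        self.head = Affine(self.spec.embedding_dim, n_speakers, self._head_rng)

    def _trunk(self, x: np.ndarray) -> np.ndarray:
        """(B, T, F) features -> pooled (B, 2*C*F') stats."""
        maps = x.transpose(0, 2, 1)[:, None, :, :]  # (B, 1, F, T)
        h = self.relu1.forward(self.conv1.forward(maps))
        for blk in self.blocks:
            h = blk.forward(h)
        B, C, Fr, T = h.shape
        self._trunk_shape = (B, C, Fr, T)
        seq = h.reshape(B, C * Fr, T).transpose(0, 2, 1)  # (B, T, C*F')
        return self.pool.forward(seq)

    def embed(self, features: np.ndarray) -> np.ndarray:
        x = np.asarray(features, dtype=np.float64)[None]
        if x.shape[1] < self.spec.min_frames:
            raise ArgumentError(f"need >= {self.spec.min_frames} frames, got {x.shape[1]}")
        return self.segment1.forward(self._trunk(x))[0]

    def forward_train(self, x: np.ndarray) -> np.ndarray:
        if self.head is None:
            raise ArgumentError("classification head not initialized; call set_head")
        h = self.seg_relu.forward(self.segment1.forward(self._trunk(x)))
        return self.head.forward(h)

    def backward(self, grad: np.ndarray) -> None:
        g = self.head.backward(grad)
        g = self.segment1.backward(self.seg_relu.backward(g))
        g = self.pool.backward(g)
        B, C, Fr, T = self._trunk_shape
        g = g.transpose(0, 2, 1).reshape(B, C, Fr, T)
        for blk in reversed(self.blocks):
            g = blk.backward(g)
        self.conv1.backward(self.relu1.backward(g))

    def params(self) -> list[Param]:
        out = self.conv1.params()
        for blk in self.blocks:
            out += blk.params()
        out += self.segment1.params()
        if self.head is not None:
            out += self.head.params()
        return out


def build_encoder(spec: EncoderSpec, seed: int = 0):
    """Instantiate the encoder described by ``spec`` with seeded init."""
    rng = np.random.default_rng(seed)
    if spec.kind == "tdnn":
        return TDNNEncoder(spec, rng)
    return ResNetEncoder(spec, rng)
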