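"""Architectures of the five neural feature extractors.

All networks share the fine-tuning layout: an input batch-normalization
layer, a family-specific trunk whose last activation is the *feature layer*,
and a softmax classification head that is discarded after training (the
autoencoder's feature layer is its encoder output and its "head" is the
decoder).  Three presets are provided: ``opportunity`` (T=64 multichannel
sliding windows), ``unimib`` (T=151 triaxial event-centered windows) and
``tiny`` (a desk-scale configuration used throughout the test-suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import SpecError
from .layers import (BatchNormChannels, Conv, Dense, ExpandDims, Flatten,
                     Layer, LSTMLayer, MaxPoolTime, MeanSquaredError, ReLU,
                     SoftmaxCrossEntropy, TimeFlatten)

FAMILIES = ("mlp", "cnn", "lstm", "hybrid", "ae")


@dataclass(frozen=True)
class ConvBlock:
    """One convolution-ReLU-maxpool block."""

    f_T: int            # kernel time extent
    f_S: int            # kernel sensor extent (1 = per-channel, S = cross-sensor)
    n_kernels: int
    stride: int = 1
    p_T: int = 2        # pool time extent (1 = no pooling)
    p_S: int = 1

    def __post_init__(self):
        if min(self.f_T, self.f_S, self.n_kernels, self.stride,
               self.p_T, self.p_S) < 1:
            raise SpecError("convolution block dimensions must be positive")
        if self.stride != 1 or self.p_S != 1:
            raise SpecError("only time stride 1 and sensor pool 1 are supported")


@dataclass(frozen=True)
class ArchitectureSpec:
    family: str
    dense_sizes: tuple[int, ...] = ()        # MLP hidden widths
    conv_blocks: tuple[ConvBlock, ...] = ()  # CNN / hybrid trunk
    lstm_dim: int = 0                        # output dim of cells, both layers
    dense_size: int = 0                      # trunk-final dense width
    ae_hidden: int = 0                       # encoder width

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise SpecError(f"unknown model family {self.family!r}")


def _presets() -> dict[str, dict[str, ArchitectureSpec]]:
    return {
        "opportunity": {
            "mlp": ArchitectureSpec("mlp", dense_sizes=(2000, 2000, 2000)),
            "cnn": ArchitectureSpec("cnn", conv_blocks=(
                ConvBlock(11, 1, 50, p_T=2), ConvBlock(10, 1, 40, p_T=3),
                ConvBlock(6, 1, 30, p_T=1)), dense_size=1000),
            "lstm": ArchitectureSpec("lstm", lstm_dim=600, dense_size=512),
            "hybrid": ArchitectureSpec("hybrid", conv_blocks=(
                ConvBlock(11, 1, 50, p_T=2),), lstm_dim=600, dense_size=512),
            "ae": ArchitectureSpec("ae", ae_hidden=5000),
        },
        "unimib": {
            "mlp": ArchitectureSpec("mlp", dense_sizes=(6000, 6000, 6000)),
            "cnn": ArchitectureSpec("cnn", conv_blocks=(
                ConvBlock(32, 3, 100, p_T=2),), dense_size=6000),
            "lstm": ArchitectureSpec("lstm", lstm_dim=1000, dense_size=6000),
            "hybrid": ArchitectureSpec("hybrid", conv_blocks=(
                ConvBlock(32, 3, 100, p_T=2),), lstm_dim=1000, dense_size=6000),
            "ae": ArchitectureSpec("ae", ae_hidden=6000),
        },
        "tiny": {
            "mlp": ArchitectureSpec("mlp", dense_sizes=(32, 32, 32)),
            "cnn": ArchitectureSpec("cnn", conv_blocks=(
                ConvBlock(5, 1, 8, p_T=2),), dense_size=32),
            "lstm": ArchitectureSpec("lstm", lstm_dim=16, dense_size=32),
            "hybrid": ArchitectureSpec("hybrid", conv_blocks=(
                ConvBlock(5, 1, 8, p_T=2),), lstm_dim=16, dense_size=32),
            "ae": ArchitectureSpec("ae", ae_hidden=32),
        },
    }


PRESETS = _presets()


def get_preset(preset: str, family: str) -> ArchitectureSpec:
    try:
        return PRESETS[preset][family]
    except KeyError:
        raise SpecError(f"no preset {preset!r} for family {family!r}") from None


def conv_time_length(L: int, f_T: int, stride: int, p_T: int) -> int:
    """Output time length of one valid-convolution + non-overlapping-pool block.

    ``floor((floor((L - f_T) / stride) + 1) / p_T)``: valid convolution, then
    pooling with the partial trailing window dropped.
    """
    if L < f_T:
        raise SpecError(f"input length {L} shorter than kernel {f_T}")
    if stride < 1 or p_T < 1:
        raise SpecError("stride and pool size must be >= 1")
    return ((L - f_T) // stride + 1) // p_T


class Model:
    """A trunk (feature extractor) plus a detachable head."""

    def __init__(self, trunk: list[Layer], head: list[Layer], family: str,
                 T: int, S: int, n_classes: int, feature_dim: int,
                 lstm_steps: int | None = None):
        self.trunk = trunk
        self.head = head
        self.family = family
        self.T, self.S, self.n_classes = T, S, n_classes
        self.feature_dim = feature_dim
        self.lstm_steps = lstm_steps
        self.loss = MeanSquaredError() if family == "ae" else SoftmaxCrossEntropy()

    # -- plumbing ----------------------------------------------------------
    def params(self):
        out = []
        for layer in self.trunk + self.head:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.trunk + self.head:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.trunk + self.head):
            dout = layer.backward(dout)
        return dout

    def feature_forward(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode activations of the feature layer (head removed)."""
        for layer in self.trunk:
            x = layer.forward(x, train=False)
        return x


def build_model(spec: ArchitectureSpec, T: int, S: int, n_classes: int,
                seed: int = 0) -> Model:
    """Instantiate an untrained model for ``T x S`` frames.

    Raises :class:`SpecError` naming the offending block whenever a derived
    time length would drop below one sample.
    """
    rng = np.random.default_rng(seed)
    fam = spec.family

    if fam == "mlp":
        sizes = spec.dense_sizes
        if len(sizes) != 3:
            raise SpecError("MLP preset needs three hidden widths")
        trunk: list[Layer] = [BatchNormChannels(S), Flatten()]
        d = T * S
        for h in sizes:
            trunk += [Dense(d, h, rng), ReLU()]
            d = h
        return Model(trunk, [Dense(d, n_classes, rng)], fam, T, S, n_classes,
                     feature_dim=d)

    if fam in ("cnn", "hybrid"):
        trunk = [BatchNormChannels(S), ExpandDims()]
        L, S_cur, C = T, S, 1
        for k, blk in enumerate(spec.conv_blocks, start=1):
            if L < blk.f_T:
                raise SpecError(
                    f"conv block {k}: time length {L} < kernel {blk.f_T}")
            if S_cur < blk.f_S:
                raise SpecError(
                    f"conv block {k}: sensor extent {S_cur} < kernel {blk.f_S}")
            trunk += [Conv(blk.f_T, blk.f_S, C, blk.n_kernels, rng), ReLU()]
            L = (L - blk.f_T) // blk.stride + 1
            S_cur = S_cur - blk.f_S + 1
            C = blk.n_kernels
            if blk.p_T > 1:
                trunk.append(MaxPoolTime(blk.p_T))
                L //= blk.p_T
            if L < 1:
                raise SpecError(f"conv block {k}: pooled time length is 0")
        if fam == "cnn":
            trunk += [Flatten(), Dense(L * S_cur * C, spec.dense_size, rng), ReLU()]
            return Model(trunk, [Dense(spec.dense_size, n_classes, rng)],
                         fam, T, S, n_classes, feature_dim=spec.dense_size)
        H = spec.lstm_dim
        trunk += [
            TimeFlatten(),
            LSTMLayer(S_cur * C, H, rng, return_sequences=True),
            LSTMLayer(H, H, rng, return_sequences=False),
            Dense(H, spec.dense_size, rng), ReLU(),
        ]
        return Model(trunk, [Dense(spec.dense_size, n_classes, rng)],
                     fam, T, S, n_classes, feature_dim=spec.dense_size,
                     lstm_steps=L)

    if fam == "lstm":
        H = spec.lstm_dim
        trunk = [
            BatchNormChannels(S),
            LSTMLayer(S, H, rng, return_sequences=True),
            LSTMLayer(H, H, rng, return_sequences=False),
            Dense(H, spec.dense_size, rng), ReLU(),
        ]
        return Model(trunk, [Dense(spec.dense_size, n_classes, rng)],
                     fam, T, S, n_classes, feature_dim=spec.dense_size,
                     lstm_steps=T)

    if fam == "ae":
        d = T * S
        trunk = [Flatten(), Dense(d, spec.ae_hidden, rng), ReLU()]
        # decoder output is linear: inputs are signed sensor values
        head = [Dense(spec.ae_hidden, d, rng)]
        return Model(trunk, head, fam, T, S, n_classes, feature_dim=spec.ae_hidden)

    raise SpecError(f"unknown family {fam!r}")
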