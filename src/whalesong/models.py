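"""The two classifier architectures, built from declarative configs.

Both operate on 125x50x3 standardized feature images and emit two-class
probabilities over (humpback, no_call).

The compact CNN stacks four convolutional blocks (16/32/64/64 filters with
6x6 / 4x4 / 3x3 / 3x3 kernels; tanh then ReLU activations; 2x2 max pooling,
batch norm and decreasing dropout in the first three blocks, a plain
convolution + flatten in the fourth) under a dense-64 / dense-2-softmax
head.  Convolutions use 'same' padding so the 6x6 kernel is valid at the
125x50 input through all blocks.

The ViT tiles the image into 90 non-overlapping 8x8 patches (15x6 grid;
5 remainder rows and 2 columns are dropped), embeds each 192-float token to
dimension 64, adds a learned positional embedding, and runs 4 pre-norm
encoder blocks (4-head attention with per-head key dim 64, MLP 128->64 with
GELU).  The head is global average pooling over tokens, an MLP of 2048 and
1024 GELU units with dropout 0.3, and a 2-way softmax.  No class token is
used (average pooling makes one redundant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

INPUT_SHAPE = (125, 50, 3)
CLASS_NAMES = ("humpback", "no_call")


@dataclass(frozen=True)
class CNNConfig:
    input_shape: tuple[int, int, int] = INPUT_SHAPE
    #: (filters, kernel, activation, pool?, batchnorm?, dropout) per block
    blocks: tuple = (
        (16, 6, "tanh", True, True, 0.5),
        (32, 4, "relu", True, True, 0.4),
        (64, 3, "relu", True, True, 0.3),
        (64, 3, "linear", False, False, 0.2),
    )
    dense_units: int = 64
    n_classes: int = 2


@dataclass(frozen=True)
class ViTConfig:
    input_shape: tuple[int, int, int] = INPUT_SHAPE
    patch: int = 8
    embed_dim: int = 64
    n_layers: int = 4
    n_heads: int = 4
    key_dim: int = 64
    attn_dropout: float = 0.1
    mlp_units: tuple[int, ...] = (128, 64)
    mlp_dropout: float = 0.1
    head_units: tuple[int, ...] = (2048, 1024)
    head_dropout: float = 0.3
    n_classes: int = 2

    @property
    def n_patches(self) -> int:
        return (self.input_shape[0] // self.patch) * (self.input_shape[1] // self.patch)

    @property
    def token_len(self) -> int:
        return self.patch * self.patch * self.input_shape[2]


def extract_patches(img: np.ndarray, patch: int = 8, stride: int | None = None) -> np.ndarray:
    """Flattened non-overlapping patches of one image, raster order.

    ``img`` is HxWxC; the stride equals the patch size (VALID tiling) and
    remainder rows/columns are dropped.  A 125x50x3 image yields 90 vectors
    of length 192.
    """
    if stride is not None and stride != patch:
        raise ValueError("only stride == patch (non-overlapping tiling) is supported")
    img = np.asarray(img)
    if img.ndim != 3:
        raise ValueError(f"expected an HxWxC image, got shape {img.shape}")
    h, w, c = img.shape
    gh, gw = h // patch, w // patch
    if gh == 0 or gw == 0:
        raise ValueError(f"image {img.shape} smaller than one {patch}x{patch} patch")
    layer = nn.PatchExtract(patch)
    return layer.forward(img[None])[0]


class PretrainedBackboneAdapter:
    """Wrap an externally supplied pretrained classifier behind the
    package's predict interface.

    ``backbone`` is any callable mapping a (n, 125, 50, 3) float batch to
    (n, 2) class probabilities — e.g. a transfer-learning model served from
    another framework.  No pretrained weights ship with this package; the
    adapter only provides the seam.
    """

    def __init__(self, backbone, name: str = "pretrained"):
        self.backbone = backbone
        self.name = name

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        p = np.asarray(self.backbone(np.asarray(x, dtype=np.float32)), dtype=np.float64)
        if p.ndim != 2 or p.shape[1] != 2:
            raise ValueError(f"backbone must return (n, 2) probabilities, got {p.shape}")
        return p


_ACTIVATIONS = {"tanh": nn.Tanh, "relu": nn.ReLU, "linear": None}


def build_cnn(config: CNNConfig = CNNConfig(), seed: int = 0) -> nn.Model:
    """Build the compact CNN; identical seeds give identical initial weights."""
    rng = np.random.default_rng(seed)
    h, w, c = config.input_shape
    layers: list[nn.Layer] = []
    c_in = c
    for filters, kernel, act, pool, batchnorm, dropout in config.blocks:
        if kernel > min(h, w):
            raise ValueError(f"kernel {kernel} too large for feature map {h}x{w}")
        layers.append(nn.Conv2D(c_in, filters, kernel, rng))
        if _ACTIVATIONS.get(act, "missing") == "missing":
            raise ValueError(f"unknown activation {act!r}")
        if _ACTIVATIONS[act] is not None:
            layers.append(_ACTIVATIONS[act]())
        if pool:
            layers.append(nn.MaxPool2D())
            h, w = h // 2, w // 2
            if h == 0 or w == 0:
                raise ValueError("input too small: pooling collapsed a dimension")
        if batchnorm:
            layers.append(nn.BatchNorm(filters))
        if dropout > 0:
            layers.append(nn.Dropout(dropout))
        c_in = filters
    layers.append(nn.Flatten())
    flat = h * w * c_in
    layers.append(nn.Dense(flat, config.dense_units, rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dense(config.dense_units, config.n_classes, rng))
    layers.append(nn.Softmax())
    return nn.Model(layers, name="compact_cnn")


def build_vit(config: ViTConfig = ViTConfig(), seed: int = 0) -> nn.Model:
    """Build the patch-embedding transformer classifier."""
    if config.embed_dim <= 0 or config.n_heads <= 0 or config.key_dim <= 0:
        raise ValueError("embed_dim, n_heads and key_dim must be positive")
    if config.mlp_units[-1] != config.embed_dim:
        raise ValueError(
            "the last encoder MLP unit must equal embed_dim so the residual connection types match"
        )
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = [
        nn.PatchExtract(config.patch),
        nn.Dense(config.token_len, config.embed_dim, rng),
        nn.PositionalEmbedding(config.n_patches, config.embed_dim, rng),
    ]
    for _ in range(config.n_layers):
        attn = nn.Residual(
            [
                nn.LayerNorm(config.embed_dim),
                nn.MultiHeadAttention(
                    config.embed_dim, config.n_heads, config.key_dim, config.attn_dropout, rng
                ),
            ]
        )
        mlp_inner: list[nn.Layer] = [nn.LayerNorm(config.embed_dim)]
        d_in = config.embed_dim
        for units in config.mlp_units:
            mlp_inner += [nn.Dense(d_in, units, rng), nn.GELU(), nn.Dropout(config.mlp_dropout)]
            d_in = units
        layers += [attn, nn.Residual(mlp_inner)]
    layers += [nn.LayerNorm(config.embed_dim), nn.GlobalAveragePool1D()]
    d_in = config.embed_dim
    for units in config.head_units:
        layers += [nn.Dense(d_in, units, rng), nn.GELU(), nn.Dropout(config.head_dropout)]
        d_in = units
    layers += [nn.Dense(d_in, config.n_classes, rng), nn.Softmax()]
    return nn.Model(layers, name="patch_vit")
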