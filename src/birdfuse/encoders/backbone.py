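"""Visual backbones: the reference 50-layer residual embedder and a tiny
trainable variant, plus image preprocessing.

``resnet50_ref`` is the standard 4-stage bottleneck stack — initial 7x7
convolution, 3x3 max pool, stages of (3, 4, 6, 3) bottleneck blocks with
channel widths (64, 128, 256, 512) x4 expansion, global average pooling and
one dense layer — 49 convolutional layers and a 2048-dimensional embedding.
``tiny`` is a 2-stage residual net with a configurable embedding size for
desk-scale training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import FormatError, InvalidConfigError, ModelIOError
from .layers import (
    Conv2d,
    Dense,
    GlobalAvgPool,
    MaxPool2d,
    Module,
    Param,
    ResidualBlock,
    Sequential,
)

__all__ = [
    "AugmentationConfig",
    "BackboneConfig",
    "VisualBackbone",
    "build_backbone",
    "preprocess_image",
    "visual_embed",
]

RESNET50_EMBEDDING_DIM = 2048


@dataclass(frozen=True)
class AugmentationConfig:
    """Seeded training-time augmentation: random crop (area fraction range),
    horizontal flip with probability 0.5, brightness scaling."""

    crop_area: tuple[float, float] = (0.8, 1.0)
    flip_prob: float = 0.5
    brightness: tuple[float, float] = (0.8, 1.2)


@dataclass(frozen=True)
class BackboneConfig:
    variant: str = "tiny"
    embedding_dim: int = 64
    pretrained_weights: str | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("resnet50_ref", "tiny"):
            raise InvalidConfigError(f"unknown backbone variant {self.variant!r}")
        if self.embedding_dim <= 0:
            raise InvalidConfigError(f"embedding_dim must be > 0, got {self.embedding_dim}")
        if self.variant == "resnet50_ref" and self.embedding_dim != RESNET50_EMBEDDING_DIM:
            raise InvalidConfigError(
                f"resnet50_ref emits a fixed {RESNET50_EMBEDDING_DIM}-d embedding"
            )


def _bilinear_resize(img: np.ndarray, size: int) -> np.ndarray:
    h, w = img.shape[:2]
    if h == size and w == size:
        return img.astype(np.float64)
    ys = (np.arange(size) + 0.5) * h / size - 0.5
    xs = (np.arange(size) + 0.5) * w / size - 0.5
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 1)
    y1 = np.clip(y0 + 1, 0, h - 1)
    x1 = np.clip(x0 + 1, 0, w - 1)
    wy = np.clip(ys - y0, 0.0, 1.0)[:, None, None]
    wx = np.clip(xs - x0, 0.0, 1.0)[None, :, None]
    top = img[y0][:, x0] * (1 - wx) + img[y0][:, x1] * wx
    bottom = img[y1][:, x0] * (1 - wx) + img[y1][:, x1] * wx
    return top * (1 - wy) + bottom * wy


def preprocess_image(
    image: np.ndarray,
    size: int = 224,
    augment: AugmentationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Bilinear resize to ``size x size``, values scaled into [0, 1].

    With ``augment`` set (and a seeded ``rng``): random crop of 0.8-1.0 of
    the area followed by resize, horizontal flip with p = 0.5, and a
    brightness scale drawn from [0.8, 1.2], clipped back to [0, 1].
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise FormatError(f"expected an RGB (H, W, 3) image, got shape {image.shape}")
    if image.shape[0] < 32 or image.shape[1] < 32:
        raise FormatError(f"image too small: {image.shape[:2]} (need >= 32x32)")
    if image.max() > 1.0:  # 8-bit input
        image = image / 255.0
    image = np.clip(image, 0.0, 1.0)
    if augment is not None:
        if rng is None:
            rng = np.random.default_rng(0)
        h, w = image.shape[:2]
        frac = np.sqrt(rng.uniform(*augment.crop_area))
        ch, cw = max(int(h * frac), 1), max(int(w * frac), 1)
        top = rng.integers(0, h - ch + 1)
        left = rng.integers(0, w - cw + 1)
        image = image[top : top + ch, left : left + cw]
        if rng.uniform() < augment.flip_prob:
            image = image[:, ::-1]
        image = image * rng.uniform(*augment.brightness)
    out = _bilinear_resize(image, size)
    return np.clip(out, 0.0, 1.0)


def _bottleneck(
    c_in: int, width: int, stride: int, rng: np.random.Generator
) -> ResidualBlock:
    c_out = width * 4
    inner = Sequential(
        Conv2d(c_in, width, 1, activation="relu", rng=rng),
        Conv2d(width, width, 3, stride=stride, padding="same", activation="relu", rng=rng),
        # small init keeps untrained activations bounded through 16 blocks
        Conv2d(width, c_out, 1, rng=rng, init_scale=0.1),
    )
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = Conv2d(c_in, c_out, 1, stride=stride, rng=rng)
    return ResidualBlock(inner, shortcut, post_activation="relu")


def _basic_block(c_in: int, c_out: int, stride: int, rng: np.random.Generator) -> ResidualBlock:
    inner = Sequential(
        Conv2d(c_in, c_out, 3, stride=stride, padding="same", activation="relu", rng=rng),
        Conv2d(c_out, c_out, 3, padding="same", rng=rng, init_scale=0.5),
    )
    shortcut = None
    if stride != 1 or c_in != c_out:
        shortcut = Conv2d(c_in, c_out, 1, stride=stride, rng=rng)
    return ResidualBlock(inner, shortcut, post_activation="relu")


class VisualBackbone(Module):
    """Residual feature stack + global average pool + dense embedding head."""

    def __init__(self, config: BackboneConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
        if config.variant == "resnet50_ref":
            layers: list[Module] = [
                Conv2d(3, 64, 7, stride=2, padding="same", activation="relu", rng=rng),
                MaxPool2d(3, stride=2, padding=1),
            ]
            c_in = 64
            for width, blocks, first_stride in (
                (64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2),
            ):
                for bi in range(blocks):
                    layers.append(
                        _bottleneck(c_in, width, first_stride if bi == 0 else 1, rng)
                    )
                    c_in = width * 4
            layers.append(GlobalAvgPool())
            self.stack = Sequential(*layers)
            self.head = Dense(c_in, RESNET50_EMBEDDING_DIM, rng=rng)
        else:
            self.stack = Sequential(
                Conv2d(3, 8, 3, padding="same", activation="relu", rng=rng),
                MaxPool2d(2, stride=2),
                _basic_block(8, 16, 2, rng),
                _basic_block(16, 16, 1, rng),
                GlobalAvgPool(),
            )
            self.head = Dense(16, config.embedding_dim, rng=rng)
        if config.pretrained_weights is not None:
            self.load_weights(config.pretrained_weights)

    @property
    def embedding_dim(self) -> int:
        return self.head.W.value.shape[1]

    def params(self) -> list[Param]:
        return self.stack.params() + self.head.params()

    def named_params(self, prefix: str = "") -> dict[str, Param]:
        out = self.stack.named_params(f"{prefix}stack.")
        out.update(self.head.named_params(f"{prefix}head."))
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.head.forward(self.stack.forward(x))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.stack.backward(self.head.backward(grad))

    def load_weights(self, path: str) -> None:
        """Import hook for externally supplied backbone weights (npz keyed
        by this module's parameter names)."""
        archive = np.load(path)
        named = self.named_params()
        for name, param in named.items():
            if name not in archive:
                raise ModelIOError(f"weight archive {path} is missing {name!r}")
            if archive[name].shape != param.value.shape:
                raise ModelIOError(
                    f"{name!r}: archive shape {archive[name].shape} != "
                    f"model shape {param.value.shape}"
                )
            param.value[...] = archive[name]


def build_backbone(config: BackboneConfig, seed: int = 0) -> VisualBackbone:
    return VisualBackbone(config, seed=seed)


def visual_embed(image: np.ndarray, backbone: VisualBackbone | BackboneConfig) -> np.ndarray:
    """Embed one preprocessed ``(H, W, 3)`` image; deterministic given weights."""
    if isinstance(backbone, BackboneConfig):
        backbone = build_backbone(backbone)
    return backbone.forward(np.asarray(image, dtype=np.float64))
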