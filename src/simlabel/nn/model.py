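"""A small seeded encoder-decoder segmentation network.

The reference model is a U-Net-style 3-level encoder-decoder with skip
connections (~16 base channels), intentionally compact so the framework can
be exercised on a CPU.  Any model satisfying the :class:`SegmentationModel`
contract — per-pixel class scores at input resolution — can be plugged into
the training and simulation modules instead.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Protocol

import numpy as np

from ..errors import DimensionError, ValidationError
from .tensor import Tensor, concat, conv2d, maxpool2d, relu, softmax, upsample2d

__all__ = ["SegmentationModel", "ReferenceModel", "build_reference_model"]

CHECKPOINT_VERSION = 1


class SegmentationModel(Protocol):
    """Contract for pluggable segmentation backbones."""

    n_classes: int

    def forward(self, images: np.ndarray) -> Tensor:
        """Batch (B,H,W,3) uint8 (or prenormalized float) -> (B,n,H,W) scores."""
        ...

    def parameters(self) -> list[Tensor]:
        ...


class _Conv:
    def __init__(self, rng: np.random.Generator, cin: int, cout: int, k: int):
        std = np.sqrt(2.0 / (cin * k * k))
        self.weight = Tensor(rng.normal(0.0, std, (cout, cin, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class ReferenceModel:
    """Seeded 3-level encoder-decoder with skips (see module docstring)."""

    def __init__(self, n_classes: int, width: int = 16, depth: int = 3, seed: int = 0):
        if n_classes < 2:
            raise ValidationError("a segmentation model needs at least 2 classes")
        if depth < 1:
            raise ValidationError("depth must be >= 1")
        self.n_classes = n_classes
        self.width = width
        self.depth = depth
        self.seed = seed
        rng = np.random.default_rng(seed)
        widths = [width * (2**d) for d in range(depth)]
        self.enc = []
        cin = 3
        for cw in widths:
            self.enc.append(_Conv(rng, cin, cw, 3))
            cin = cw
        self.dec = []
        for d in range(depth - 2, -1, -1):
            self.dec.append(_Conv(rng, widths[d + 1] + widths[d], widths[d], 3))
        self.head = _Conv(rng, widths[0], n_classes, 1)

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for layer in [*self.enc, *self.dec, self.head]:
            ps += [layer.weight, layer.bias]
        return ps

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    @staticmethod
    def normalize(images: np.ndarray) -> np.ndarray:
        """uint8 (B,H,W,3) -> float32 (B,3,H,W) in [-1, 1]."""
        x = np.asarray(images, dtype=np.float32) / 127.5 - 1.0
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def forward(self, images: np.ndarray | Tensor) -> Tensor:
        if isinstance(images, Tensor):
            x = images
        else:
            images = np.asarray(images)
            if images.ndim == 3:
                images = images[None]
            x = Tensor(self.normalize(images) if images.ndim == 4 and images.shape[-1] == 3
                       else images)
        h, w = x.shape[2], x.shape[3]
        div = 2 ** (self.depth - 1)
        if h % div or w % div:
            raise DimensionError(
                f"input {h}x{w} not divisible by {div} required at depth {self.depth}"
            )
        skips = []
        for d, layer in enumerate(self.enc):
            x = relu(layer(x))
            if d < self.depth - 1:
                skips.append(x)
                x = maxpool2d(x)
        for layer, skip in zip(self.dec, reversed(skips)):
            x = relu(layer(concat(upsample2d(x), skip)))
        return self.head(x)

    # convenience inference -------------------------------------------------
    def predict_probs(self, images: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities, (B,n,H,W); softmax over classes."""
        return softmax(self.forward(images), axis=1).data

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Argmax class-index maps, (B,H,W)."""
        return self.forward(images).data.argmax(axis=1)

    # checkpointing ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = {
            "version": CHECKPOINT_VERSION,
            "n_classes": self.n_classes,
            "width": self.width,
            "depth": self.depth,
            "seed": self.seed,
        }
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceModel":
        with np.load(path, allow_pickle=False) as zf:
            meta = json.loads(str(zf["__meta__"]))
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ValidationError(
                    f"checkpoint version {meta.get('version')} unsupported"
                )
            model = cls(meta["n_classes"], meta["width"], meta["depth"], meta["seed"])
            for i, p in enumerate(model.parameters()):
                data = zf[f"p{i}"]
                if data.shape != p.data.shape:
                    raise ValidationError(f"checkpoint parameter {i} shape mismatch")
                p.data = data.astype(np.float32)
        return model


def build_reference_model(
    n_classes: int, width: int = 16, depth: int = 3, seed: int = 0
) -> ReferenceModel:
    """Build the default seeded encoder-decoder model."""
    return ReferenceModel(n_classes, width=width, depth=depth, seed=seed)
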