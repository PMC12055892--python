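"""Images, index masks, palettes, and dataset manifests.

The canonical on-disk mask format is an 8-bit single-channel PNG of class
indices (row-major, origin top-left, 0-based).  RGB color masks are an
import path only, via a palette mapping hex colors to class names or
indices.  A manifest lists image/mask pairs with a fold id and the label
space they live in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import yaml
from PIL import Image

from .errors import DataError, ValidationError

__all__ = [
    "SegmentationSample",
    "ManifestEntry",
    "DatasetManifest",
    "read_mask",
    "write_mask",
    "read_image",
    "write_image",
    "load_manifest",
    "write_manifest",
    "load_sample",
    "load_palette",
]

LabelSpace = Literal["strong", "simplified"]


@dataclass
class SegmentationSample:
    """An image with its per-pixel label map and label-space tag.

    ``label_space`` is ``"strong"`` for class-level labels or ``"simplified"``
    for group-level labels; simplified samples carry the name of the grouping
    that defines their label space in ``grouping_ref``.
    """

    image: np.ndarray  # H x W x 3 uint8
    label: np.ndarray  # H x W integer indices
    label_space: LabelSpace = "strong"
    grouping_ref: str | None = None
    source_id: str = ""
    fold: int = 0

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.label.shape:
            raise ValidationError(
                f"image {self.image.shape[:2]} and label {self.label.shape} "
                f"shapes differ for sample {self.source_id!r}"
            )
        if self.label_space == "simplified" and self.grouping_ref is None:
            raise ValidationError(
                f"simplified sample {self.source_id!r} has no grouping_ref"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.label.shape


@dataclass(frozen=True)
class ManifestEntry:
    image: str
    mask: str
    fold: int
    label_space: LabelSpace = "strong"
    grouping_ref: str | None = None
    source_id: str = ""


@dataclass
class DatasetManifest:
    """A dataset description: entries, class list, optional palette/resize."""

    entries: list[ManifestEntry]
    classes: list[str]
    palette: dict[str, str] | None = None
    resize: tuple[int, int] | None = None  # (H, W), applied on load
    root: Path = field(default_factory=Path)

    @property
    def n_folds(self) -> int:
        return 1 + max(e.fold for e in self.entries) if self.entries else 0

    def fold_entries(self, fold: int) -> list[ManifestEntry]:
        return [e for e in self.entries if e.fold == fold]

    def validate(self, check_files: bool = True) -> None:
        if not self.entries:
            raise ValidationError("manifest has no entries")
        folds = sorted({e.fold for e in self.entries})
        if folds != list(range(len(folds))):
            raise ValidationError(f"fold ids {folds} are not contiguous from 0")
        ids = [e.source_id for e in self.entries if e.source_id]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate source_id(s): {dup}")
        if check_files:
            for e in self.entries:
                for p in (e.image, e.mask):
                    if not (self.root / p).exists():
                        raise ValidationError(f"referenced file missing: {self.root / p}")


# ---------------------------------------------------------------------------
# masks and images

def _parse_hex(color: str) -> tuple[int, int, int]:
    c = color.lstrip("#")
    if len(c) != 6:
        raise ValidationError(f"bad hex color {color!r}")
    return tuple(int(c[i : i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]


def load_palette(path: str | Path) -> dict[str, str]:
    """Load a JSON palette ``{hex color -> class name}``."""
    obj = json.loads(Path(path).read_text())
    if not isinstance(obj, dict):
        raise ValidationError("palette file must hold a JSON object")
    return obj


def read_mask(
    path: str | Path,
    palette: Mapping[str, str | int] | None = None,
    classes: Sequence[str] | None = None,
) -> np.ndarray:
    """Read a mask PNG as a 2-D integer index raster.

    Single-channel (``L``/``P``) PNGs are read as indices directly.  RGB masks
    require a ``palette`` mapping hex colors to class names (resolved against
    ``classes``) or to integer indices; any color outside the palette is a
    data error reporting the color and its pixel count.
    """
    img = Image.open(path)
    if img.mode in ("L", "P"):
        return np.asarray(img, dtype=np.uint8).astype(np.int64)
    if img.mode in ("I", "I;16", "F"):
        raise DataError(
            f"mask {path} has bit depth > 8 ({img.mode}); not supported without a palette"
        )
    rgb = np.asarray(img.convert("RGB"))
    if palette is None:
        raise DataError(f"mask {path} is RGB but no palette was given")
    lut: dict[tuple[int, int, int], int] = {}
    for color, target in palette.items():
        if isinstance(target, int):
            idx = target
        else:
            if classes is None:
                raise ValidationError(
                    "palette maps colors to class names; pass the ordered class list"
                )
            try:
                idx = list(classes).index(target)
            except ValueError:
                raise ValidationError(f"palette class {target!r} not in class list")
        lut[_parse_hex(color)] = idx
    flat = rgb.reshape(-1, 3)
    out = np.full(flat.shape[0], -1, dtype=np.int64)
    for color, idx in lut.items():
        out[(flat == color).all(axis=1)] = idx
    if (out < 0).any():
        colors, counts = np.unique(flat[out < 0], axis=0, return_counts=True)
        desc = ", ".join(
            f"#{r:02x}{g:02x}{b:02x} ({c} px)"
            for (r, g, b), c in zip(colors.tolist(), counts.tolist())
        )
        raise DataError(f"mask {path} contains colors not in the palette: {desc}")
    return out.reshape(rgb.shape[:2])


def write_mask(
    raster: np.ndarray, path: str | Path, palette: Mapping[str, int] | None = None
) -> None:
    """Write an index raster as an 8-bit single-channel PNG.

    With ``palette`` (hex color -> index) the PNG carries a color table for
    viewing; indices on disk are unchanged either way.
    """
    raster = np.asarray(raster)
    if raster.ndim != 2:
        raise DataError("mask raster must be 2-D")
    if raster.min() < 0 or raster.max() > 255:
        raise DataError("mask indices must fit in 8 bits (0-255)")
    img = Image.fromarray(raster.astype(np.uint8), mode="L")
    if palette is not None:
        img = img.convert("P")
        table = [0] * 768
        for color, idx in palette.items():
            r, g, b = _parse_hex(color)
            table[3 * idx : 3 * idx + 3] = [r, g, b]
        img.putpalette(table)
    img.save(path, format="PNG")


def read_image(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_image(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path, format="PNG")


def resize_image(image: np.ndarray, size_hw: tuple[int, int]) -> np.ndarray:
    """Bilinear resize for images (masks use :func:`resize_mask`)."""
    h, w = size_hw
    return np.asarray(
        Image.fromarray(np.asarray(image, dtype=np.uint8)).resize((w, h), Image.BILINEAR)
    )


def resize_mask(mask: np.ndarray, size_hw: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resize for index masks (never interpolates labels)."""
    h, w = size_hw
    out = Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="L").resize(
        (w, h), Image.NEAREST
    )
    return np.asarray(out).astype(np.int64)


# ---------------------------------------------------------------------------
# manifests

def _manifest_to_obj(manifest: DatasetManifest) -> dict:
    obj: dict = {
        "classes": list(manifest.classes),
        "entries": [
            {
                "image": e.image,
                "mask": e.mask,
                "fold": e.fold,
                "label_space": e.label_space,
                **({"grouping_ref": e.grouping_ref} if e.grouping_ref else {}),
                **({"source_id": e.source_id} if e.source_id else {}),
            }
            for e in manifest.entries
        ],
    }
    if manifest.palette:
        obj["palette"] = manifest.palette
    if manifest.resize:
        obj["resize"] = list(manifest.resize)
    return obj


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    path = Path(path)
    obj = _manifest_to_obj(manifest)
    if path.suffix == ".json":
        path.write_text(json.dumps(obj, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(obj, sort_keys=False))


def load_manifest(path: str | Path, check_files: bool = True) -> DatasetManifest:
    """Load and schema-validate a manifest (YAML or JSON).

    Entry order on disk is preserved; re-serialization is order-stable.
    """
    path = Path(path)
    text = path.read_text()
    obj = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(obj, dict) or "entries" not in obj or "classes" not in obj:
        raise ValidationError(f"manifest {path} must define 'classes' and 'entries'")
    entries = []
    for i, e in enumerate(obj["entries"]):
        try:
            entries.append(
                ManifestEntry(
                    image=e["image"],
                    mask=e["mask"],
                    fold=int(e["fold"]),
                    label_space=e.get("label_space", "strong"),
                    grouping_ref=e.get("grouping_ref"),
                    source_id=e.get("source_id", ""),
                )
            )
        except KeyError as exc:
            raise ValidationError(f"manifest entry {i} missing key {exc}") from exc
    manifest = DatasetManifest(
        entries=entries,
        classes=list(obj["classes"]),
        palette=obj.get("palette"),
        resize=tuple(obj["resize"]) if obj.get("resize") else None,
        root=path.parent,
    )
    manifest.validate(check_files=check_files)
    return manifest


def load_sample(manifest: DatasetManifest, entry: ManifestEntry) -> SegmentationSample:
    """Load one manifest entry, applying the manifest-level resize if any."""
    image = read_image(manifest.root / entry.image)
    label = read_mask(
        manifest.root / entry.mask, palette=manifest.palette, classes=manifest.classes
    )
    if manifest.resize is not None:
        image = resize_image(image, manifest.resize)
        label = resize_mask(label, manifest.resize)
    return SegmentationSample(
        image=image,
        label=label,
        label_space=entry.label_space,
        grouping_ref=entry.grouping_ref,
        source_id=entry.source_id or entry.image,
        fold=entry.fold,
    )


def load_all_samples(manifest: DatasetManifest) -> list[SegmentationSample]:
    return [load_sample(manifest, e) for e in manifest.entries]
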