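"""Seeded synthetic laparoscopy-like scenes for desk-scale experiments.

Scenes are built from *class families* whose members share a shape kind and a
base color: "tissue"-like blobs (random-walk-smoothed polygons), "organ"-like
ellipses, "tool"-like capsules that always enter from the image border, and a
background family filling residual pixels.  Families are visually well
separated (distinct base colors and shape kinds) while classes *within* a
family differ only by a small color offset, so group membership is obvious at
a glance but class identity takes finer evidence — the statistical structure
the simplified-label method assumes.

All randomness flows from a counter-based generator keyed by
``(seed, image index)`` so datasets are order-independent and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from .data_io import (
    DatasetManifest,
    ManifestEntry,
    SegmentationSample,
    write_image,
    write_manifest,
    write_mask,
)
from .errors import ValidationError
from .grouping import Grouping

__all__ = [
    "FamilySpec",
    "SceneSpec",
    "generate_scene",
    "generate_samples",
    "generate_dataset",
    "default_scene_spec",
    "secondary_scene_spec",
    "save_scene_spec",
    "load_scene_spec",
    "default_grouping",
    "scene_rng",
]

SHAPE_KINDS = ("blob", "ellipse", "capsule", "background")


@dataclass(frozen=True)
class FamilySpec:
    """One visual family: a shape kind, member classes, and a base color."""

    name: str
    shape: str  # one of SHAPE_KINDS
    classes: tuple[str, ...]
    weights: tuple[float, ...]  # per-class draw frequency
    base_color: tuple[int, int, int]
    class_offsets: tuple[tuple[int, int, int], ...] = ()
    shapes_per_scene: tuple[int, int] = (1, 3)  # inclusive range

    def __post_init__(self) -> None:
        if self.shape not in SHAPE_KINDS:
            raise ValidationError(f"unknown shape kind {self.shape!r}")
        if not self.classes:
            raise ValidationError(f"family {self.name!r} has no classes")
        if len(self.weights) != len(self.classes):
            raise ValidationError(f"family {self.name!r}: weights/classes length mismatch")
        if any(w < 0 for w in self.weights):
            raise ValidationError(f"family {self.name!r}: negative frequency weight")
        if self.class_offsets and len(self.class_offsets) != len(self.classes):
            raise ValidationError(f"family {self.name!r}: offsets/classes length mismatch")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of the scene generator.

    ``noise_sigma`` is per-pixel Gaussian noise; ``lighting_sigma`` is a
    per-scene global color shift (one draw per channel shared by every pixel
    of the scene), emulating illumination changes between frames.  Lighting
    variability is what makes *within*-family class identity data-hungry to
    learn — absolute color boundaries between sibling classes drift from
    scene to scene — while family identity stays easy, since family base
    colors are far apart.
    """

    height: int = 64
    width: int = 64
    families: tuple[FamilySpec, ...] = ()
    noise_sigma: float = 8.0
    lighting_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValidationError("scene size below 16x16 is degenerate")
        if not self.families:
            raise ValidationError("at least one family is required")
        all_classes = self.classes
        if len(set(all_classes)) != len(all_classes):
            raise ValidationError("class names must be unique across families")
        if len(all_classes) > 255:
            raise ValidationError("more than 255 classes unsupported (8-bit masks)")
        backgrounds = [f for f in self.families if f.shape == "background"]
        if len(backgrounds) != 1:
            raise ValidationError("exactly one background family is required")

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(c for f in self.families for c in f.classes)

    def class_index(self, name: str) -> int:
        return self.classes.index(name)

    def family_of_class(self) -> dict[str, str]:
        return {c: f.name for f in self.families for c in f.classes}


def scene_rng(seed: int, image_index: int) -> np.random.Generator:
    """Counter-style generator keyed by ``(seed, image index)``."""
    return np.random.default_rng(np.random.SeedSequence([seed, image_index]))


# ---------------------------------------------------------------------------
# shape rasterisers

def _blob_mask(rng: np.random.Generator, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    cy = rng.uniform(0.2 * h, 0.8 * h)
    cx = rng.uniform(0.2 * w, 0.8 * w)
    base_r = rng.uniform(0.10, 0.22) * min(h, w)
    k = 24
    wobble = gaussian_filter1d(rng.normal(0.0, 1.0, k), sigma=2.5, mode="wrap")
    radii = base_r * np.clip(1.0 + 0.45 * wobble, 0.35, 1.9)
    ang = np.linspace(0.0, 2 * np.pi, k, endpoint=False) + rng.uniform(0, 2 * np.pi)
    rr, cc = draw_polygon(cy + radii * np.sin(ang), cx + radii * np.cos(ang), (h, w))
    return rr, cc


def _ellipse_mask(rng: np.random.Generator, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    cy = rng.uniform(0.2 * h, 0.8 * h)
    cx = rng.uniform(0.2 * w, 0.8 * w)
    ry = rng.uniform(0.07, 0.18) * h
    rx = rng.uniform(0.09, 0.22) * w
    rot = rng.uniform(0, np.pi)
    rr, cc = draw_ellipse(cy, cx, ry, rx, shape=(h, w), rotation=rot)
    return rr, cc


def _capsule_mask(rng: np.random.Generator, h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    # a thick segment anchored on the border, pointing inward
    side = rng.integers(0, 4)
    if side == 0:  # top
        p0 = np.array([0.0, rng.uniform(0, w - 1)])
        inward = np.pi / 2
    elif side == 1:  # bottom
        p0 = np.array([h - 1.0, rng.uniform(0, w - 1)])
        inward = -np.pi / 2
    elif side == 2:  # left
        p0 = np.array([rng.uniform(0, h - 1), 0.0])
        inward = 0.0
    else:  # right
        p0 = np.array([rng.uniform(0, h - 1), w - 1.0])
        inward = np.pi
    ang = inward + rng.uniform(-0.6, 0.6)
    length = rng.uniform(0.35, 0.85) * min(h, w)
    p1 = p0 + length * np.array([np.sin(ang), np.cos(ang)])
    radius = rng.uniform(0.025, 0.06) * min(h, w) + 1.0
    yy, xx = np.mgrid[0:h, 0:w]
    d = p1 - p0
    t = ((yy - p0[0]) * d[0] + (xx - p0[1]) * d[1]) / (d @ d)
    t = np.clip(t, 0.0, 1.0)
    dist2 = (yy - (p0[0] + t * d[0])) ** 2 + (xx - (p0[1] + t * d[1])) ** 2
    return np.nonzero(dist2 <= radius**2)


_SHAPE_FNS = {"blob": _blob_mask, "ellipse": _ellipse_mask, "capsule": _capsule_mask}


def _default_offsets(n: int) -> tuple[tuple[int, int, int], ...]:
    # symmetric small offsets around the family base color
    span = [(-9, -9, -9), (9, 9, 9), (-9, 9, -9), (9, -9, 9)]
    return tuple(span[i % len(span)] for i in range(n))


def generate_scene(spec: SceneSpec, rng: np.random.Generator) -> SegmentationSample:
    """Render one scene: image plus an exactly consistent class-index mask.

    Shape families are drawn in spec order with tools (capsules) always last,
    so later shapes occlude earlier ones; the background family fills residual
    pixels.  Per-pixel colors are family base color + class offset + a
    per-scene lighting shift + Gaussian noise of standard deviation
    ``spec.noise_sigma``.
    """
    h, w = spec.height, spec.width
    lighting = rng.normal(0.0, spec.lighting_sigma, 3) if spec.lighting_sigma > 0 else 0.0
    classes = spec.classes
    bg_family = next(f for f in spec.families if f.shape == "background")
    bg_weights = np.asarray(bg_family.weights, dtype=float)
    bg_cls = bg_family.classes[
        int(rng.choice(len(bg_family.classes), p=bg_weights / bg_weights.sum()))
    ]
    label = np.full((h, w), spec.class_index(bg_cls), dtype=np.int64)

    drawn: list[tuple[int, np.ndarray, np.ndarray]] = []
    families = [f for f in spec.families if f.shape != "background"]
    families.sort(key=lambda f: f.shape == "capsule")  # capsules (tools) on top
    for fam in families:
        lo, hi = fam.shapes_per_scene
        n_shapes = int(rng.integers(lo, hi + 1))
        weights = np.asarray(fam.weights, dtype=float)
        probs = weights / weights.sum()
        for _ in range(n_shapes):
            cls = fam.classes[int(rng.choice(len(fam.classes), p=probs))]
            rr, cc = _SHAPE_FNS[fam.shape](rng, h, w)
            idx = spec.class_index(cls)
            label[rr, cc] = idx
            drawn.append((idx, rr, cc))

    # paint colors after all occlusion is resolved
    colors = np.zeros((len(classes), 3), dtype=float)
    for fam in spec.families:
        offsets = fam.class_offsets or _default_offsets(len(fam.classes))
        for cls, off in zip(fam.classes, offsets):
            colors[spec.class_index(cls)] = np.asarray(fam.base_color, float) + off
    image = colors[label] + lighting
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return SegmentationSample(image=image, label=label, label_space="strong")


def generate_samples(
    spec: SceneSpec, n_images: int, k_folds: int, seed: int
) -> list[SegmentationSample]:
    """Generate ``n_images`` scenes in memory with round-robin fold ids."""
    if n_images < k_folds:
        raise ValidationError(f"n_images={n_images} < k_folds={k_folds}")
    samples = []
    for i in range(n_images):
        s = generate_scene(spec, scene_rng(seed, i))
        s.source_id = f"scene_{i:05d}"
        s.fold = i % k_folds
        samples.append(s)
    return samples


def generate_dataset(
    spec: SceneSpec, n_images: int, k_folds: int, out_dir: str | Path, seed: int
) -> DatasetManifest:
    """Write a dataset (images, masks, manifest) to ``out_dir``.

    Two calls with the same seed produce byte-identical files.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    entries = []
    for s in generate_samples(spec, n_images, k_folds, seed):
        img_rel = f"images/{s.source_id}.png"
        mask_rel = f"masks/{s.source_id}.png"
        write_image(s.image, out_dir / img_rel)
        write_mask(s.label, out_dir / mask_rel)
        entries.append(
            ManifestEntry(
                image=img_rel,
                mask=mask_rel,
                fold=s.fold,
                label_space="strong",
                source_id=s.source_id,
            )
        )
    manifest = DatasetManifest(entries=entries, classes=list(spec.classes), root=out_dir)
    write_manifest(manifest, out_dir / "manifest.yaml")
    return manifest


# ---------------------------------------------------------------------------
# scene-spec config round-trip

def save_scene_spec(spec: SceneSpec, path) -> None:
    """Write a scene spec as YAML (round-trips losslessly)."""
    import yaml

    obj = {
        "height": spec.height,
        "width": spec.width,
        "noise_sigma": spec.noise_sigma,
        "lighting_sigma": spec.lighting_sigma,
        "families": [
            {
                "name": f.name,
                "shape": f.shape,
                "classes": list(f.classes),
                "weights": list(f.weights),
                "base_color": list(f.base_color),
                **({"class_offsets": [list(o) for o in f.class_offsets]}
                   if f.class_offsets else {}),
                "shapes_per_scene": list(f.shapes_per_scene),
            }
            for f in spec.families
        ],
    }
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))


def load_scene_spec(path) -> SceneSpec:
    """Read a YAML scene spec written by :func:`save_scene_spec`."""
    import yaml

    obj = yaml.safe_load(Path(path).read_text())
    try:
        families = tuple(
            FamilySpec(
                name=f["name"],
                shape=f["shape"],
                classes=tuple(f["classes"]),
                weights=tuple(f["weights"]),
                base_color=tuple(f["base_color"]),
                class_offsets=tuple(tuple(o) for o in f.get("class_offsets", ())),
                shapes_per_scene=tuple(f.get("shapes_per_scene", (1, 3))),
            )
            for f in obj["families"]
        )
        return SceneSpec(
            height=int(obj.get("height", 64)),
            width=int(obj.get("width", 64)),
            families=families,
            noise_sigma=float(obj.get("noise_sigma", 8.0)),
            lighting_sigma=float(obj.get("lighting_sigma", 10.0)),
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"scene spec config invalid: {exc}") from exc


# ---------------------------------------------------------------------------
# default study conditions

def default_scene_spec(
    height: int = 64, width: int = 64, noise_sigma: float = 8.0,
    lighting_sigma: float = 10.0,
) -> SceneSpec:
    """The default primary dataset: 6 foreground classes in 3 families + background.

    Family base colors are far apart (≳60 grey levels) so group membership is
    obvious without expertise.  The second class of each family is *rare*
    (frequency weight 0.4–0.5 vs 1.0) and differs from its sibling only by a
    ±9-per-channel color offset, against pixel noise σ=8 and a per-scene
    lighting shift σ=10; resolving sibling identity therefore takes many
    class-labeled scenes — the expertise-bound part of the task — while
    group-level structure is learnable from any labeled scene.
    """
    families = (
        FamilySpec(
            "tissue", "blob", ("tissue_a", "tissue_b"), (1.0, 0.4), (172, 76, 64),
            shapes_per_scene=(2, 4),
        ),
        FamilySpec(
            "organ", "ellipse", ("organ_a", "organ_b"), (1.0, 0.4), (206, 150, 142),
            shapes_per_scene=(1, 3),
        ),
        FamilySpec(
            "tool", "capsule", ("tool_a", "tool_b"), (1.0, 0.5), (92, 102, 144),
            shapes_per_scene=(1, 2),
        ),
        FamilySpec("backdrop", "background", ("background",), (1.0,), (28, 26, 32)),
    )
    return SceneSpec(height=height, width=width, families=families,
                     noise_sigma=noise_sigma, lighting_sigma=lighting_sigma)


def default_grouping() -> Grouping:
    """Class→group assignment matching :func:`default_scene_spec` families."""
    spec = default_scene_spec()
    fam = spec.family_of_class()
    group_of_family = {"tissue": "tissue", "organ": "organ", "tool": "tool", "backdrop": "background"}
    assignment = {c: group_of_family[fam[c]] for c in spec.classes}
    return Grouping(spec.classes, ("tissue", "organ", "tool", "background"), assignment)


def secondary_scene_spec(
    height: int = 64, width: int = 64, noise_sigma: float = 8.0,
    lighting_sigma: float = 10.0,
) -> SceneSpec:
    """A secondary dataset with a class set disjoint from the primary one.

    Emulates a porcine robotic-surgery dataset: kidney-like blobs, an
    intestine-like ellipse class, instrument capsules, and an "other tissue"
    backdrop.  The whole field of view is tissue except for the instruments
    (there is no dark void as in the primary scenes), and colors stay in the
    same biological-vs-instrument palette, so the shared biological /
    non-biological structure transfers without contradicting the primary
    dataset's background supervision.
    """
    families = (
        FamilySpec(
            "parenchyma", "blob", ("kidney_parenchyma", "covered_kidney"), (1.0, 0.6),
            (158, 88, 78), shapes_per_scene=(1, 3),
        ),
        FamilySpec(
            "intestine", "ellipse", ("small_intestine",), (1.0,), (196, 142, 128),
            shapes_per_scene=(1, 2),
        ),
        FamilySpec(
            "instrument", "capsule", ("probe", "needle_driver"), (1.0, 0.7),
            (104, 110, 136), shapes_per_scene=(1, 2),
        ),
        FamilySpec("other_tissue", "background", ("other_tissue",), (1.0,),
                   (148, 94, 82)),
    )
    return SceneSpec(height=height, width=width, families=families,
                     noise_sigma=noise_sigma, lighting_sigma=lighting_sigma)
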