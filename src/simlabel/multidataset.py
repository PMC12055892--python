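"""Joint training on datasets with incompatible (even disjoint) class sets.

A :class:`SharedGroupSpec` maps both class sets onto one ordered list of
shared groups (e.g. "biological", "non_biological", plus the primary
dataset's background group, which may receive no secondary class).  The
secondary dataset is converted into simplified labels over the shared
groups; during training, the model's primary-class predictions are
projected through the *primary* grouping matrix, so secondary data
supervises the model without changing its output space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .data_io import SegmentationSample, resize_image, resize_mask
from .errors import DimensionError, ValidationError
from .grouping import Grouping, GroupMatrix, build_matrix, simplify_map
from .losses import LossConfig
from .nn.model import ReferenceModel
from .training import EpochPlan, TrainResult, make_schedule, train

__all__ = [
    "SharedGroupSpec",
    "build_shared_matrices",
    "convert_secondary",
    "joint_train",
    "load_shared_spec",
    "save_shared_spec",
]

SHARED_GROUPING_REF = "shared"


@dataclass(frozen=True)
class SharedGroupSpec:
    """Maps two class sets onto one ordered list of shared groups.

    Both maps must be total over their class sets and target groups from
    ``groups``; on the secondary side groups may be empty (the primary
    background group typically receives no secondary class).
    """

    groups: tuple[str, ...]
    primary_classes: tuple[str, ...]
    secondary_classes: tuple[str, ...]
    primary_map: Mapping[str, str]
    secondary_map: Mapping[str, str]

    def primary_grouping(self) -> Grouping:
        return Grouping(
            self.primary_classes, self.groups, dict(self.primary_map),
            allow_empty_groups=True,
        )

    def secondary_grouping(self) -> Grouping:
        return Grouping(
            self.secondary_classes, self.groups, dict(self.secondary_map),
            allow_empty_groups=True,
        )


def build_shared_matrices(spec: SharedGroupSpec) -> tuple[GroupMatrix, GroupMatrix]:
    """Grouping matrices for both datasets over the same group order.

    Returns ``(M_primary, M_secondary)`` with shapes ``m x n_primary`` and
    ``m x n_secondary``; both have unit column sums, and rows follow
    ``spec.groups`` in both.
    """
    for name, mapping, classes in (
        ("primary", spec.primary_map, spec.primary_classes),
        ("secondary", spec.secondary_map, spec.secondary_classes),
    ):
        for cls in classes:
            if cls not in mapping:
                raise ValidationError(f"{name} class {cls!r} is unmapped")
            if mapping[cls] not in spec.groups:
                raise ValidationError(
                    f"{name} class {cls!r} maps to group {mapping[cls]!r} "
                    "absent from the shared group order"
                )
    return build_matrix(spec.primary_grouping()), build_matrix(spec.secondary_grouping())


def convert_secondary(
    samples: Sequence[SegmentationSample],
    spec: SharedGroupSpec,
    resize: tuple[int, int] | None = None,
) -> list[SegmentationSample]:
    """Convert secondary-dataset samples into simplified labels over shared groups.

    Masks are re-indexed from secondary class indices to shared group
    indices; with ``resize`` images are downscaled bilinearly and masks by
    nearest neighbor (so feature scales match the primary dataset).
    """
    _, M_sec = build_shared_matrices(spec)
    out = []
    for s in samples:
        label = simplify_map(s.label, M_sec)
        image = s.image
        if resize is not None:
            image = resize_image(image, resize)
            label = resize_mask(label, resize)
        out.append(
            SegmentationSample(
                image=image,
                label=label,
                label_space="simplified",
                grouping_ref=SHARED_GROUPING_REF,
                source_id=s.source_id,
                fold=s.fold,
            )
        )
    return out


def joint_train(
    model: ReferenceModel,
    primary_strong: Sequence[SegmentationSample],
    secondary_simplified: Sequence[SegmentationSample],
    spec: SharedGroupSpec,
    strategy: str = "mixed",
    seed: int = 0,
    plan: EpochPlan | None = None,
    loss_cfg: LossConfig = LossConfig(),
    batch_size: int = 8,
) -> TrainResult:
    """Train a primary-space model on strong primary data plus converted
    secondary data.

    Secondary batches are scored through ``M_primary`` (the model predicts
    primary classes; the loss compares their group projection with the
    converted labels), so the evaluation class space never changes.  The
    mixed strategy is the default.
    """
    if model.n_classes != len(spec.primary_classes):
        raise DimensionError(
            f"model predicts {model.n_classes} classes but the shared spec "
            f"lists {len(spec.primary_classes)} primary classes"
        )
    if plan is None:
        plan = make_schedule(strategy)
    return train(
        model,
        list(primary_strong),
        list(secondary_simplified),
        plan,
        seed,
        groupings={SHARED_GROUPING_REF: spec.primary_grouping()},
        loss_cfg=loss_cfg,
        batch_size=batch_size,
    )


# ---------------------------------------------------------------------------
# config round-trip

def save_shared_spec(spec: SharedGroupSpec, path: str | Path) -> None:
    obj = {
        "groups": list(spec.groups),
        "primary_classes": list(spec.primary_classes),
        "secondary_classes": list(spec.secondary_classes),
        "primary": dict(spec.primary_map),
        "secondary": dict(spec.secondary_map),
    }
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(obj, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(obj, sort_keys=False))


def load_shared_spec(path: str | Path) -> SharedGroupSpec:
    path = Path(path)
    text = path.read_text()
    obj = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    try:
        return SharedGroupSpec(
            groups=tuple(obj["groups"]),
            primary_classes=tuple(obj["primary_classes"]),
            secondary_classes=tuple(obj["secondary_classes"]),
            primary_map=dict(obj["primary"]),
            secondary_map=dict(obj["secondary"]),
        )
    except KeyError as exc:
        raise ValidationError(f"shared-group spec missing key {exc}") from exc
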