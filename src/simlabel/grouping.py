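"""Label-space algebra: groupings, grouping matrices, and simplification.

A *grouping* assigns each of ``n`` classes to exactly one of ``m`` groups and
is realised by a binary ``m x n`` matrix ``M`` with unit column sums.
Multiplying a class probability vector ``y`` by ``M`` yields a group
probability vector ``y' = M y``; the map conserves the element-wise sum,
preserves nonnegativity, and sends 1-hot vectors to 1-hot vectors, so
group-level ("simplified") labels remain valid targets for any
classification loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import DataError, DimensionError, ValidationError

__all__ = [
    "Grouping",
    "GroupMatrix",
    "build_matrix",
    "identity_grouping",
    "simplify_vector",
    "simplify_map",
    "compose_groupings",
    "load_grouping",
    "save_grouping",
    "cholecseg8k_grouping",
    "PROB_SUM_TOL",
]

#: tolerance used when checking that an input vector is a probability vector
PROB_SUM_TOL = 1e-6


@dataclass(frozen=True)
class Grouping:
    """An assignment of each class to exactly one group.

    Parameters
    ----------
    classes
        Ordered class names (length ``n``); order defines class indices.
    groups
        Ordered group names (length ``m``); order defines group indices and
        is the order groups first appear in a config, not alphabetical.
    assignment
        Map ``class name -> group name``, total over ``classes``.
    allow_empty_groups
        Permit groups with no member class.  Off by default (catches typos);
        needed for multi-dataset groupings where one shared group receives no
        class from one side.
    """

    classes: tuple[str, ...]
    groups: tuple[str, ...]
    assignment: Mapping[str, str] = field(hash=False)
    allow_empty_groups: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "assignment", dict(self.assignment))
        if len(set(self.classes)) != len(self.classes):
            raise ValidationError("duplicate class names in grouping")
        if len(set(self.groups)) != len(self.groups):
            raise ValidationError("duplicate group names in grouping")
        if not self.groups:
            raise ValidationError("grouping needs at least one group")
        for cls in self.classes:
            if cls not in self.assignment:
                raise ValidationError(f"class {cls!r} is not assigned to any group")
            grp = self.assignment[cls]
            if grp not in self.groups:
                raise ValidationError(
                    f"class {cls!r} is assigned to unknown group {grp!r}"
                )
        extra = set(self.assignment) - set(self.classes)
        if extra:
            raise ValidationError(f"assignment mentions unknown classes: {sorted(extra)}")
        if not self.allow_empty_groups:
            used = set(self.assignment.values())
            empty = [g for g in self.groups if g not in used]
            if empty:
                raise ValidationError(
                    f"groups {empty} have no member class "
                    "(pass allow_empty_groups=True to permit this)"
                )

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_index_of(self, cls: str) -> int:
        return self.groups.index(self.assignment[cls])

    def class_to_group_indices(self) -> np.ndarray:
        """Lookup table ``class index -> group index`` (length ``n``)."""
        gidx = {g: i for i, g in enumerate(self.groups)}
        return np.array([gidx[self.assignment[c]] for c in self.classes], dtype=np.int64)

    @property
    def is_identity(self) -> bool:
        return (
            self.n_classes == self.n_groups
            and all(self.assignment[c] == g for c, g in zip(self.classes, self.groups))
        )


@dataclass(frozen=True)
class GroupMatrix:
    """The binary ``m x n`` matrix realising a :class:`Grouping`.

    ``entries[i, j] == 1`` iff class ``j`` belongs to group ``i``; every
    column sums to exactly 1.
    """

    entries: np.ndarray
    group_labels: tuple[str, ...]
    class_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries)
        object.__setattr__(self, "entries", entries)
        if entries.ndim != 2:
            raise ValidationError("group matrix must be 2-D")
        if entries.shape != (len(self.group_labels), len(self.class_labels)):
            raise ValidationError("group matrix shape does not match its labels")
        if not np.isin(entries, (0, 1)).all():
            raise ValidationError("group matrix entries must be 0 or 1")
        colsums = entries.sum(axis=0)
        if not (colsums == 1).all():
            bad = [self.class_labels[j] for j in np.nonzero(colsums != 1)[0]]
            raise ValidationError(f"columns of classes {bad} do not sum to 1")

    @property
    def n_groups(self) -> int:
        return self.entries.shape[0]

    @property
    def n_classes(self) -> int:
        return self.entries.shape[1]

    def class_to_group_indices(self) -> np.ndarray:
        return self.entries.argmax(axis=0).astype(np.int64)


def build_matrix(grouping: Grouping) -> GroupMatrix:
    """Realise a grouping as its ``m x n`` binary matrix."""
    m, n = grouping.n_groups, grouping.n_classes
    entries = np.zeros((m, n), dtype=np.float64)
    lut = grouping.class_to_group_indices()
    entries[lut, np.arange(n)] = 1.0
    return GroupMatrix(entries, grouping.groups, grouping.classes)


def identity_grouping(classes: Sequence[str]) -> Grouping:
    """Each class its own group, in the same order (``M = I``)."""
    classes = tuple(classes)
    return Grouping(classes, classes, {c: c for c in classes})


def _as_matrix(M: GroupMatrix | np.ndarray) -> np.ndarray:
    return M.entries if isinstance(M, GroupMatrix) else np.asarray(M)


def simplify_vector(
    y: np.ndarray, M: GroupMatrix | np.ndarray, check_probability: bool = False
) -> np.ndarray:
    """Transform a class vector into a group vector, ``y' = M y``.

    Conserves the element-wise sum and nonnegativity; sends 1-hot vectors to
    1-hot vectors.  With ``check_probability`` the input must sum to 1 within
    :data:`PROB_SUM_TOL` and be nonnegative.
    """
    mat = _as_matrix(M)
    y = np.asarray(y)
    if y.shape != (mat.shape[1],):
        raise DimensionError(
            f"vector of length {y.shape} does not match matrix with {mat.shape[1]} classes"
        )
    if check_probability:
        if (y < 0).any():
            raise DataError("probability vector has negative entries")
        if abs(float(y.sum()) - 1.0) > PROB_SUM_TOL:
            raise DataError(f"probability vector sums to {y.sum()}, not 1")
    return mat @ y


def simplify_map(
    label_map: np.ndarray, M: GroupMatrix | np.ndarray
) -> np.ndarray:
    """Simplify a segmentation map pixel-wise.

    ``label_map`` may be a 2-D integer class-index raster (result: group-index
    raster) or an ``H x W x n`` per-pixel probability map (result:
    ``H x W x m``, each pixel multiplied by ``M``).
    """
    mat = _as_matrix(M)
    label_map = np.asarray(label_map)
    if np.issubdtype(label_map.dtype, np.integer):
        n = mat.shape[1]
        if label_map.size and (bad := (label_map < 0) | (label_map >= n)).any():
            loc = tuple(int(v) for v in np.argwhere(bad)[0])
            raise DataError(
                f"class index {int(label_map[loc])} at pixel {loc} is outside [0, {n})"
            )
        lut = mat.argmax(axis=0).astype(label_map.dtype)
        return lut[label_map]
    if label_map.ndim < 1 or label_map.shape[-1] != mat.shape[1]:
        raise DimensionError(
            f"probability map with last axis {label_map.shape[-1:]} does not match "
            f"matrix with {mat.shape[1]} classes"
        )
    return np.einsum("mn,...n->...m", mat, label_map)


def compose_groupings(outer: Grouping, inner: Grouping) -> Grouping:
    """Coarsen ``inner`` by a grouping ``outer`` over its groups.

    Requires ``outer.classes == inner.groups``; the matrix of the result is
    the product ``matrix(outer) @ matrix(inner)``.
    """
    if tuple(outer.classes) != tuple(inner.groups):
        raise ValidationError(
            "outer grouping's classes must equal inner grouping's groups "
            f"(got {outer.classes} vs {inner.groups})"
        )
    assignment = {c: outer.assignment[inner.assignment[c]] for c in inner.classes}
    return Grouping(
        inner.classes,
        outer.groups,
        assignment,
        allow_empty_groups=outer.allow_empty_groups or inner.allow_empty_groups,
    )


# ---------------------------------------------------------------------------
# config round-trip

def _grouping_to_obj(grouping: Grouping) -> dict:
    groups = {
        g: [c for c in grouping.classes if grouping.assignment[c] == g]
        for g in grouping.groups
    }
    obj = {"classes": list(grouping.classes), "groups": groups}
    if grouping.allow_empty_groups:
        obj["allow_empty_groups"] = True
    return obj


def _grouping_from_obj(obj: Mapping) -> Grouping:
    try:
        classes = list(obj["classes"])
        groups_map = obj["groups"]
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"grouping config missing key: {exc}") from exc
    assignment: dict[str, str] = {}
    for grp, members in groups_map.items():
        for cls in members or []:
            if cls in assignment:
                raise ValidationError(f"class {cls!r} listed under two groups")
            assignment[cls] = grp
    return Grouping(
        tuple(classes),
        tuple(groups_map.keys()),
        assignment,
        allow_empty_groups=bool(obj.get("allow_empty_groups", False)),
    )


def save_grouping(grouping: Grouping, path: str | Path) -> None:
    """Write a grouping config (YAML or JSON by extension). Round-trips losslessly."""
    path = Path(path)
    obj = _grouping_to_obj(grouping)
    if path.suffix == ".json":
        path.write_text(json.dumps(obj, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(obj, sort_keys=False))


def load_grouping(path: str | Path) -> Grouping:
    """Read a grouping config written by :func:`save_grouping`."""
    path = Path(path)
    text = path.read_text()
    obj = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _grouping_from_obj(obj)


def cholecseg8k_grouping() -> Grouping:
    """The standard 8-class laparoscopic grouping into four visual groups.

    Abdominal wall, fat and gastrointestinal tract form the Tissue group;
    liver and gallbladder the Organ group; grasper and L-hook the Tool
    group; background stays its own group.
    """
    classes = (
        "abdominal_wall",
        "fat",
        "gastrointestinal_tract",
        "liver",
        "gallbladder",
        "grasper",
        "l_hook",
        "background",
    )
    assignment = {
        "abdominal_wall": "tissue",
        "fat": "tissue",
        "gastrointestinal_tract": "tissue",
        "liver": "organ",
        "gallbladder": "organ",
        "grasper": "tool",
        "l_hook": "tool",
        "background": "background",
    }
    return Grouping(classes, ("tissue", "organ", "tool", "background"), assignment)
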