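"""Simulated annotator teams, cross-validated experiments, and comparisons.

The training data is split into ``k`` folds, each "authored" by one
simulated annotator.  Medical annotators produce strong (class-level)
labels; non-medical annotators produce simplified (group-level) labels by
pushing the ground truth through the grouping matrix — the simulation
assumes perfect annotators at their respective granularity.  Meaningful
training needs at least one medical annotator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .data_io import SegmentationSample
from .errors import DegenerateInputError, ValidationError
from .grouping import Grouping, build_matrix, simplify_map
from .losses import LossConfig, per_class_dice
from .nn.model import ReferenceModel, build_reference_model
from .training import EpochPlan, make_schedule, train

__all__ = [
    "TeamComposition",
    "ExperimentResult",
    "assign_roles",
    "materialize_team_dataset",
    "crossval_experiment",
    "paired_t_test",
]


@dataclass(frozen=True)
class TeamComposition:
    """Counts of medical (strong-label) and non-medical (simplified-label)
    annotators; the team size equals the number of training folds used."""

    n_medical: int
    n_nonmedical: int

    def __post_init__(self) -> None:
        if self.n_medical < 1:
            raise ValidationError(
                "at least one medical annotator is required for meaningful training"
            )
        if self.n_nonmedical < 0:
            raise ValidationError("n_nonmedical must be >= 0")

    @property
    def total(self) -> int:
        return self.n_medical + self.n_nonmedical

    @property
    def name(self) -> str:
        return f"{self.n_medical}M{self.n_nonmedical}NM"

    @classmethod
    def parse(cls, text: str) -> "TeamComposition":
        """Parse strings like ``"1M3NM"`` or ``"2M"``."""
        m = re.fullmatch(r"(\d+)M(?:(\d+)NM)?", text.strip(), flags=re.IGNORECASE)
        if not m:
            raise ValidationError(f"cannot parse team composition {text!r}")
        return cls(int(m.group(1)), int(m.group(2) or 0))


def assign_roles(
    folds: Sequence[int], comp: TeamComposition, rotation: int = 0
) -> dict[int, str]:
    """Assign each training fold a label space, deterministically.

    Exactly ``comp.n_medical`` folds become strong.  ``rotation`` rotates the
    fold order so averaging over rotations covers every assignment.
    """
    folds = list(folds)
    if len(folds) != comp.total:
        raise ValidationError(
            f"{len(folds)} folds but team of {comp.total} members "
            f"({comp.n_medical}M + {comp.n_nonmedical}NM)"
        )
    rotated = folds[rotation % len(folds):] + folds[: rotation % len(folds)]
    return {
        f: ("strong" if i < comp.n_medical else "simplified")
        for i, f in enumerate(rotated)
    }


def materialize_team_dataset(
    samples: Sequence[SegmentationSample],
    roles: dict[int, str],
    grouping: Grouping,
) -> tuple[list[SegmentationSample], list[SegmentationSample]]:
    """Split samples into strong and simplified pools per the role map.

    Simplified-fold labels are pushed through the grouping matrix; strong
    folds are untouched.  Inputs are never mutated.  Samples whose fold is
    not in the role map (e.g. the test fold) are dropped.
    """
    missing = set()
    for s in samples:
        missing.update(set(np.unique(s.label)) - set(range(grouping.n_classes)))
    if missing:
        raise ValidationError(
            f"grouping covers {grouping.n_classes} classes but masks contain "
            f"indices {sorted(int(i) for i in missing)}"
        )
    M = build_matrix(grouping)
    strong: list[SegmentationSample] = []
    simplified: list[SegmentationSample] = []
    for s in samples:
        role = roles.get(s.fold)
        if role is None:
            continue
        if role == "strong":
            strong.append(s)
        else:
            simplified.append(
                SegmentationSample(
                    image=s.image,
                    label=simplify_map(s.label, M),
                    label_space="simplified",
                    grouping_ref="team",
                    source_id=s.source_id,
                    fold=s.fold,
                )
            )
    return strong, simplified


@dataclass
class ExperimentResult:
    """Mean and per-class Dice per (repeat, CV split) for one composition."""

    composition: TeamComposition
    strategy: str
    seed: int
    samples: list[dict] = field(default_factory=list)  # repeat, fold, mean_dice, per_class

    @property
    def dice_values(self) -> np.ndarray:
        return np.array([s["mean_dice"] for s in self.samples])

    @property
    def mean(self) -> float:
        return float(self.dice_values.mean())

    @property
    def sd(self) -> float:
        v = self.dice_values
        return float(v.std(ddof=1)) if len(v) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "composition": self.composition.name,
            "strategy": self.strategy,
            "seed": self.seed,
            "n_samples": len(self.samples),
            "mean_dice": self.mean,
            "sd_dice": self.sd,
        }


def crossval_experiment(
    samples: Sequence[SegmentationSample],
    grouping: Grouping,
    comp: TeamComposition,
    strategy: str = "mixed",
    repeats: int = 1,
    seed: int = 0,
    splits: Sequence[int] | None = None,
    rotation: int = 0,
    model_factory: Callable[[int, int], ReferenceModel] | None = None,
    plan: EpochPlan | None = None,
    loss_cfg: LossConfig = LossConfig(),
    batch_size: int = 8,
) -> ExperimentResult:
    """Cross-validated team experiment.

    For each repeat and each CV split, one fold is held out for testing; the
    team's ``comp.total`` members each label one of the remaining folds
    (strong for medical, simplified for non-medical), the model trains with
    the chosen strategy, and mean/per-class Dice is measured on the held-out
    fold.  ``splits`` restricts which held-out folds to run (desk-scale runs
    use a subset); ``repeats`` re-runs each split with a fresh model seed.
    """
    samples = list(samples)
    n_classes = grouping.n_classes
    folds = sorted({s.fold for s in samples})
    if comp.total > len(folds) - 1:
        raise ValidationError(
            f"team of {comp.total} needs {comp.total} training folds but only "
            f"{len(folds) - 1} are available besides the test fold"
        )
    if splits is None:
        splits = folds
    if model_factory is None:
        model_factory = lambda n, s: build_reference_model(n, seed=s)
    if plan is None:
        plan = make_schedule(strategy)
    result = ExperimentResult(composition=comp, strategy=strategy, seed=seed)
    for repeat in range(repeats):
        for test_fold in splits:
            train_folds = [f for f in folds if f != test_fold][: comp.total]
            roles = assign_roles(train_folds, comp, rotation=rotation)
            strong, simplified = materialize_team_dataset(samples, roles, grouping)
            run_seed = (seed * 10_000 + repeat * 100 + test_fold) % (2**31 - 1)
            model = model_factory(n_classes, run_seed)
            train(
                model, strong, simplified, plan, run_seed,
                groupings={"team": grouping}, loss_cfg=loss_cfg,
                batch_size=batch_size,
            )
            test = [s for s in samples if s.fold == test_fold]
            preds = model.predict(np.stack([s.image for s in test]))
            targets = np.stack([s.label for s in test])
            dice = per_class_dice(preds, targets, n_classes)
            result.samples.append(
                {
                    "repeat": repeat,
                    "fold": int(test_fold),
                    "mean_dice": dice.mean,
                    "per_class": dice.per_class.tolist(),
                }
            )
    return result


def paired_t_test(dice_a: Sequence[float], dice_b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed paired Student's t test on matched Dice samples.

    Returns ``(t, p)`` with ``t = mean(d) / (sd(d)/sqrt(n))`` for the paired
    differences ``d = a - b`` and ``p`` from the t distribution with ``n-1``
    degrees of freedom.
    """
    a = np.asarray(dice_a, dtype=float)
    b = np.asarray(dice_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"paired samples differ in length: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValidationError("paired t test needs at least 2 pairs")
    if np.all(a == b):
        raise DegenerateInputError("all paired differences are zero; t is undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
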