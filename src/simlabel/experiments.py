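"""Preconfigured desk-scale experiments on the synthetic datasets.

These functions pin the package's default study conditions — scene spec,
dataset size, fold layout, schedule — so the same experiment is run
identically from the test suite, the acceptance script, and the CLI.

Team trend
    200 scenes of the default 64x64 primary spec split into 5 folds of 40; fold 0
    is held out, the team labels folds 1..4 (strong for medical members,
    simplified through the default grouping for non-medical members); the
    reference model trains with the mixed strategy and is scored by mean
    Dice on fold 0.

Multi-dataset trend
    100 primary scenes with all four training folds strong, optionally
    joined by 40 scenes of the disjoint-class secondary spec converted to
    shared biological / non-biological groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .losses import per_class_dice
from .multidataset import SharedGroupSpec, convert_secondary, joint_train
from .nn.model import build_reference_model
from .teams import TeamComposition, crossval_experiment
from .training import make_schedule, train
from .synthetic import (
    default_grouping,
    default_scene_spec,
    generate_samples,
    secondary_scene_spec,
)

__all__ = [
    "TrendResult",
    "team_trend_experiment",
    "multidataset_trend_experiment",
    "default_shared_spec",
    "N_TEAM_IMAGES",
    "N_MULTI_IMAGES",
    "K_FOLDS",
    "N_SECONDARY",
]

N_TEAM_IMAGES = 200
N_MULTI_IMAGES = 100
K_FOLDS = 5
N_SECONDARY = 40
TEST_FOLD = 0


@dataclass
class TrendResult:
    """Per-seed mean Dice for each experimental arm."""

    arms: dict[str, dict[int, float]] = field(default_factory=dict)

    def record(self, arm: str, seed: int, dice: float) -> None:
        self.arms.setdefault(arm, {})[seed] = dice

    def seed_values(self, arm: str) -> np.ndarray:
        return np.array([v for _, v in sorted(self.arms[arm].items())])

    def mean(self, arm: str) -> float:
        return float(self.seed_values(arm).mean())

    def wins(self, arm_a: str, arm_b: str) -> int:
        """Number of seeds where ``arm_a`` scores strictly above ``arm_b``."""
        return int((self.seed_values(arm_a) > self.seed_values(arm_b)).sum())

    @property
    def n_seeds(self) -> int:
        return len(next(iter(self.arms.values())))


def team_trend_experiment(
    seeds=(1, 2, 3, 4, 5),
    compositions=((1, 0), (1, 3), (2, 0)),
    strategy: str = "mixed",
) -> TrendResult:
    """Run the annotator-team comparison across seeds.

    Each seed regenerates the dataset and retrains from scratch; each arm is
    one team composition (medical, non-medical).  Returns per-seed mean Dice
    keyed by composition name (e.g. ``"1M3NM"``).
    """
    spec = default_scene_spec()
    grouping = default_grouping()
    result = TrendResult()
    for seed in seeds:
        samples = generate_samples(spec, N_TEAM_IMAGES, K_FOLDS, seed)
        for n_med, n_non in compositions:
            comp = TeamComposition(n_med, n_non)
            exp = crossval_experiment(
                samples, grouping, comp, strategy=strategy,
                repeats=1, seed=seed, splits=[TEST_FOLD],
            )
            result.record(comp.name, seed, exp.mean)
    return result


def default_shared_spec() -> SharedGroupSpec:
    """Shared groups joining the default primary and secondary scene specs.

    Everything biological on both sides maps to "biological", instruments to
    "non_biological", and the primary background keeps its own group, which
    receives no secondary class (the secondary backdrop is tissue, so it
    maps to "biological").
    """
    primary = default_scene_spec().classes
    secondary = secondary_scene_spec().classes
    primary_map = {
        c: ("non_biological" if c.startswith("tool") else
            "primary_background" if c == "background" else "biological")
        for c in primary
    }
    secondary_map = {
        c: ("non_biological" if c in ("probe", "needle_driver") else "biological")
        for c in secondary
    }
    return SharedGroupSpec(
        groups=("biological", "non_biological", "primary_background"),
        primary_classes=primary,
        secondary_classes=secondary,
        primary_map=primary_map,
        secondary_map=secondary_map,
    )


def multidataset_trend_experiment(seeds=(1, 2, 3, 4, 5)) -> TrendResult:
    """Compare primary-only training against joint training per seed.

    Both arms use the same model initialisation and all four strong primary
    folds; the joint arm adds the converted secondary dataset as simplified
    data under the mixed strategy.  Arms: ``"primary_only"``, ``"joint"``.
    """
    primary_spec = default_scene_spec()
    shared = default_shared_spec()
    n_classes = len(primary_spec.classes)
    plan = make_schedule("mixed")
    result = TrendResult()
    for seed in seeds:
        primary = generate_samples(primary_spec, N_MULTI_IMAGES, K_FOLDS, seed)
        strong = [s for s in primary if s.fold != TEST_FOLD]
        test = [s for s in primary if s.fold == TEST_FOLD]
        secondary = generate_samples(
            secondary_scene_spec(), N_SECONDARY, 1, seed + 50_000
        )
        converted = convert_secondary(secondary, shared)
        images = np.stack([s.image for s in test])
        targets = np.stack([s.label for s in test])
        for arm, pool in (("primary_only", []), ("joint", converted)):
            model = build_reference_model(n_classes, seed=seed)
            if pool:
                joint_train(model, strong, pool, shared, seed=seed, plan=plan)
            else:
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # simplified epochs skipped
                    train(model, strong, [], plan, seed)
            dice = per_class_dice(model.predict(images), targets, n_classes)
            result.record(arm, seed, dice.mean)
    return result
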