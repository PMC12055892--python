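"""Training strategies over mixed pools of strong and simplified samples.

Strong labels live in class space (n channels) and simplified labels in
group space (m channels), so the two kinds cannot share a minibatch; the
schedule therefore interleaves *epochs* of one kind or the other.  Three
strategies are provided, each 25 epochs long with a learning-rate drop for
the last 5 strong epochs:

==================  =============================================================
strong_first        10 strong, 10 simplified, 5 strong @ low lr
simplified_first    10 simplified, 10 strong, 5 strong @ low lr
mixed               10 alternating (strong, simplified) pairs, 5 strong @ low lr
==================  =============================================================

Defaults: Adam, base lr 0.0005 dropping to 0.000125, batch size 8.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import SegmentationSample
from .errors import ConfigurationError, ValidationError
from .grouping import Grouping, GroupMatrix, build_matrix
from .losses import LossConfig, combo_loss, simplified_loss
from .nn.model import ReferenceModel
from .nn.optim import Adam
from .nn.tensor import softmax

__all__ = [
    "Stage",
    "TrainingSchedule",
    "EpochSpec",
    "EpochPlan",
    "make_schedule",
    "run_epoch",
    "train",
    "TrainResult",
    "STRATEGIES",
    "BASE_LR",
    "LOW_LR",
]

BASE_LR = 5e-4
LOW_LR = 1.25e-4
STRATEGIES = ("strong_first", "simplified_first", "mixed")


@dataclass(frozen=True)
class Stage:
    kind: str  # "strong" | "simplified" | "mixed"
    epochs: int
    lr: float

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValidationError("every stage needs at least one epoch")
        if self.lr <= 0:
            raise ValidationError("learning rate must be positive")


@dataclass(frozen=True)
class TrainingSchedule:
    """Ordered stage plan plus optimizer settings."""

    stages: tuple[Stage, ...]
    optimizer: str = "adam"
    batch_size: int = 8
    seed: int = 0

    def expand(self, strong_first_in_pair: bool = True) -> "EpochPlan":
        """Flatten stages into per-epoch (kind, lr) entries; mixed stages
        alternate strong/simplified epochs, strong first by default."""
        epochs: list[EpochSpec] = []
        for stage in self.stages:
            if stage.kind == "mixed":
                pair = ("strong", "simplified") if strong_first_in_pair else (
                    "simplified", "strong")
                kinds = [pair[i % 2] for i in range(stage.epochs)]
            else:
                kinds = [stage.kind] * stage.epochs
            for kind in kinds:
                epochs.append(EpochSpec(len(epochs), kind, stage.lr))
        return EpochPlan(tuple(epochs))


@dataclass(frozen=True)
class EpochSpec:
    index: int
    kind: str  # "strong" | "simplified"
    lr: float


@dataclass(frozen=True)
class EpochPlan:
    epochs: tuple[EpochSpec, ...]

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    @property
    def kinds(self) -> list[str]:
        return [e.kind for e in self.epochs]

    @property
    def lrs(self) -> list[float]:
        return [e.lr for e in self.epochs]


def make_schedule(
    strategy: str,
    base_lr: float = BASE_LR,
    low_lr: float = LOW_LR,
    stage_epochs: tuple[int, int, int] = (10, 10, 5),
    strong_first_in_pair: bool = True,
) -> EpochPlan:
    """Expand one of the three named strategies into its epoch plan.

    With the default stage lengths (10, 10, 5) every plan is 25 epochs long
    and drops the learning rate from ``base_lr`` to ``low_lr`` for the final
    strong stage.
    """
    e1, e2, e3 = stage_epochs
    if strategy == "strong_first":
        stages = (Stage("strong", e1, base_lr), Stage("simplified", e2, base_lr),
                  Stage("strong", e3, low_lr))
    elif strategy == "simplified_first":
        stages = (Stage("simplified", e1, base_lr), Stage("strong", e2, base_lr),
                  Stage("strong", e3, low_lr))
    elif strategy == "mixed":
        stages = (Stage("mixed", e1 + e2, base_lr), Stage("strong", e3, low_lr))
    else:
        raise ValidationError(
            f"unknown strategy {strategy!r}; valid strategies: {', '.join(STRATEGIES)}"
        )
    return TrainingSchedule(stages).expand(strong_first_in_pair=strong_first_in_pair)


# ---------------------------------------------------------------------------
# epoch and run loops

def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def run_epoch(
    model: ReferenceModel,
    optimizer: Adam,
    samples: list[SegmentationSample],
    lr: float,
    rng: np.random.Generator,
    loss_cfg: LossConfig = LossConfig(),
    M: GroupMatrix | np.ndarray | None = None,
    batch_size: int = 8,
) -> float:
    """One shuffled pass over a pool of samples sharing one label space.

    Strong batches are scored with the Combo loss in class space; simplified
    batches with the simplified loss through the pool's grouping matrix
    ``M``.  Mixing label spaces in one call is a contract violation (the
    target tensors would not share a channel count).  Returns the mean batch
    loss.
    """
    if not samples:
        raise ConfigurationError("run_epoch called with an empty pool")
    spaces = {s.label_space for s in samples}
    if len(spaces) > 1:
        raise ConfigurationError(
            f"pool mixes label spaces {sorted(spaces)}; strong and simplified "
            "targets differ in channel count and cannot share an epoch"
        )
    space = spaces.pop()
    if space == "simplified" and M is None:
        raise ConfigurationError("simplified pool requires its grouping matrix M")
    images = np.stack([s.image for s in samples])
    labels = np.stack([s.label for s in samples])
    losses = []
    for idx in _batches(len(samples), batch_size, rng):
        probs = softmax(model.forward(images[idx]), axis=1)
        if space == "simplified":
            loss = simplified_loss(probs, labels[idx], M, loss_cfg)
        else:
            loss = combo_loss(probs, labels[idx], loss_cfg)
        optimizer.zero_grad()
        loss.backward()
        optimizer.step(lr=lr)
        losses.append(loss.item())
    return float(np.mean(losses))


@dataclass
class TrainResult:
    model: ReferenceModel
    log: list[dict] = field(default_factory=list)

    def log_rows(self) -> list[dict]:
        return list(self.log)


def _partition_simplified(
    pool: list[SegmentationSample],
) -> list[tuple[str | None, list[SegmentationSample]]]:
    """Group simplified samples by their grouping so each sub-pool has one M."""
    order: list[str | None] = []
    buckets: dict[str | None, list[SegmentationSample]] = {}
    for s in pool:
        key = s.grouping_ref if s.label_space == "simplified" else None
        if key not in buckets:
            buckets[key] = []
            order.append(key)
        buckets[key].append(s)
    return [(k, buckets[k]) for k in order]


def train(
    model: ReferenceModel,
    strong_pool: list[SegmentationSample],
    simplified_pool: list[SegmentationSample],
    plan: EpochPlan,
    seed: int,
    groupings: dict[str, Grouping] | None = None,
    loss_cfg: LossConfig = LossConfig(),
    batch_size: int = 8,
) -> TrainResult:
    """Execute an epoch plan over a strong pool and a simplified pool.

    Meaningful training requires at least some strong labels, so an empty
    strong pool is a configuration error.  An empty *simplified* pool
    degrades gracefully: simplified epochs are skipped with a warning and
    strong epochs still run (the all-medical baseline reuses this code
    path).  Per-epoch mean losses are logged with their data kind; the whole
    run is deterministic given ``seed`` (shuffling is epoch-keyed).
    """
    if not strong_pool:
        raise ConfigurationError(
            "strong pool is empty: meaningful training requires at least some "
            "strong labels (at least one medical annotator)"
        )
    groupings = groupings or {}
    matrices: dict[str | None, GroupMatrix | None] = {}
    partitions = _partition_simplified(simplified_pool)
    for key, part in partitions:
        if key is None:
            matrices[key] = None  # strong-tagged samples in the simplified slot
        elif key in groupings:
            matrices[key] = build_matrix(groupings[key])
        else:
            raise ConfigurationError(
                f"simplified samples reference unknown grouping {key!r}"
            )
    optimizer = Adam(model.parameters())
    warned = False
    result = TrainResult(model=model)
    for epoch in plan:
        rng = np.random.default_rng(np.random.SeedSequence([seed, epoch.index]))
        if epoch.kind == "strong":
            loss = run_epoch(
                model, optimizer, strong_pool, epoch.lr, rng, loss_cfg,
                batch_size=batch_size,
            )
        else:
            if not simplified_pool:
                if not warned:
                    warnings.warn(
                        "simplified pool is empty; simplified epochs are skipped",
                        stacklevel=2,
                    )
                    warned = True
                continue
            losses = [
                run_epoch(
                    model, optimizer, part, epoch.lr, rng, loss_cfg,
                    M=matrices[key], batch_size=batch_size,
                )
                for key, part in partitions
            ]
            loss = float(np.mean(losses))
        result.log.append(
            {"epoch": epoch.index, "kind": epoch.kind, "lr": epoch.lr, "loss": loss}
        )
    return result
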