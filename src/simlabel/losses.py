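"""Combo loss, the simplified (group-level) loss, and Dice metrics.

The training objective is the Combo loss

``L = alpha * mCE - (1 - alpha) * DSC``

where ``mCE`` is a modified cross-entropy weighting false negatives against
false positives by ``beta`` and ``DSC`` is the soft Dice coefficient averaged
over classes.  The simplified loss evaluates the same objective after
projecting the class-space prediction into group space with a grouping
matrix: ``Loss = L(M yhat, y')``.  With ``M = I`` it reduces exactly to the
plain loss on strong labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, DimensionError, ValidationError
from .grouping import GroupMatrix
from .nn.tensor import Tensor, channel_project, clip, log

__all__ = [
    "LossConfig",
    "combo_loss",
    "simplified_loss",
    "per_class_dice",
    "mean_dice",
    "DiceResult",
]


@dataclass(frozen=True)
class LossConfig:
    """Parameters of the Combo loss.

    alpha
        Mix between the cross-entropy term and the Dice term, in [0, 1].
    beta
        False-negative vs false-positive weight inside the modified CE.
    eps
        Dice smoothing constant.
    clip
        Probabilities are clamped to [clip, 1 - clip] before logs.
    """

    alpha: float = 0.5
    beta: float = 0.5
    eps: float = 1e-6
    clip: float = 1e-7

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValidationError("alpha and beta must lie in [0, 1]")
        if self.eps <= 0 or self.clip <= 0:
            raise ValidationError("eps and clip must be positive")


_PROB_TOL = 1e-4


def _prep(pred, target, n_expected: int | None = None) -> tuple[Tensor, np.ndarray]:
    pred = pred if isinstance(pred, Tensor) else Tensor(pred)
    if pred.data.ndim == 3:  # (n,H,W) single sample
        pred = Tensor(pred.data[None], _parents=(pred,), _backward=lambda g: (g[0],)) \
            if pred.requires_grad else Tensor(pred.data[None])
        target = np.asarray(target)[None]
    target = np.asarray(target)
    if pred.data.ndim != 4:
        raise DimensionError(f"prediction must be (B,n,H,W), got {pred.data.shape}")
    if target.shape != (pred.data.shape[0], *pred.data.shape[2:]):
        raise DimensionError(
            f"target shape {target.shape} does not match prediction {pred.data.shape}"
        )
    n = pred.data.shape[1]
    if n_expected is not None and n != n_expected:
        raise DimensionError(f"prediction has {n} channels, expected {n_expected}")
    if target.min() < 0 or target.max() >= n:
        raise DataError(f"target indices outside [0, {n})")
    if pred.data.min() < -_PROB_TOL or pred.data.max() > 1.0 + _PROB_TOL:
        raise DataError("predicted probabilities outside [0, 1] beyond tolerance")
    return pred, target


def _one_hot(target: np.ndarray, n: int) -> np.ndarray:
    """(B,H,W) indices -> (B,n,H,W) float32 one-hot."""
    b, h, w = target.shape
    oh = np.zeros((b, n, h * w), dtype=np.float32)
    flat = target.reshape(b, h * w)
    np.put_along_axis(oh, flat[:, None, :], 1.0, axis=1)
    return oh.reshape(b, n, h, w)


def combo_loss(pred, target: np.ndarray, cfg: LossConfig = LossConfig()) -> Tensor:
    """Combo loss of a per-pixel probability map against an index map.

    ``pred`` is (B,n,H,W) probabilities (numpy array or autodiff Tensor);
    ``target`` (B,H,W) class indices.  Returns a scalar Tensor,
    differentiable in ``pred``; its minimum approaches ``-(1 - alpha)`` for a
    perfect prediction.
    """
    pred, target = _prep(pred, target)
    n = pred.data.shape[1]
    t = _one_hot(target, n)
    p = clip(pred, cfg.clip, 1.0 - cfg.clip)
    # modified CE: mean over pixels of the class-summed weighted log terms
    ce_terms = t * log(p) * cfg.beta + (1.0 - t) * log(1.0 - p) * (1.0 - cfg.beta)
    m_ce = -(ce_terms.sum(axis=1).mean())
    # soft Dice per class, counts pooled over the whole batch
    inter = (p * t).sum(axis=(0, 2, 3))
    denom = p.sum(axis=(0, 2, 3)) + t.sum(axis=(0, 2, 3))
    dsc = ((inter * 2.0 + cfg.eps) / (denom + cfg.eps)).mean()
    return m_ce * cfg.alpha - dsc * (1.0 - cfg.alpha)


def simplified_loss(
    pred,
    target: np.ndarray,
    M: GroupMatrix | np.ndarray,
    cfg: LossConfig = LossConfig(),
) -> Tensor:
    """Combo loss evaluated in group space: ``L(M yhat, y')``.

    ``pred`` is a class-space probability map (B,n,H,W); ``target`` a
    group-index map (B,H,W).  The prediction is projected through the
    constant grouping matrix pixel-wise, so gradients flow back into class
    space.  With the identity matrix this equals :func:`combo_loss` exactly.
    """
    mat = M.entries if isinstance(M, GroupMatrix) else np.asarray(M)
    pred = pred if isinstance(pred, Tensor) else Tensor(pred)
    if pred.data.ndim == 3:
        pred = Tensor(pred.data[None])
        target = np.asarray(target)[None]
    if pred.data.ndim != 4:
        raise DimensionError(f"prediction must be (B,n,H,W), got {pred.data.shape}")
    if pred.data.shape[1] != mat.shape[1]:
        raise DimensionError(
            f"class axis: prediction has {pred.data.shape[1]} classes, "
            f"matrix expects {mat.shape[1]}"
        )
    target = np.asarray(target)
    if target.size and target.max() >= mat.shape[0]:
        raise DimensionError(
            f"group axis: target index {int(target.max())} outside the "
            f"{mat.shape[0]} groups of the matrix"
        )
    grouped = channel_project(mat, pred)
    return combo_loss(grouped, target, cfg)


# ---------------------------------------------------------------------------
# Dice metrics

@dataclass(frozen=True)
class DiceResult:
    """Per-class Dice with supports; classes absent from both prediction and
    target over the whole evaluation set score 1 by convention and are
    flagged in ``absent``."""

    per_class: np.ndarray
    support_pred: np.ndarray
    support_target: np.ndarray
    absent: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.per_class.mean())

    def rows(self, classes: list[str] | None = None) -> list[dict]:
        names = classes or [str(i) for i in range(len(self.per_class))]
        return [
            {
                "class": names[i],
                "dice": float(self.per_class[i]),
                "support": int(self.support_target[i]),
                "absent": bool(self.absent[i]),
            }
            for i in range(len(self.per_class))
        ]


def _stack_maps(maps) -> np.ndarray:
    if isinstance(maps, np.ndarray):
        return maps.reshape(-1)
    return np.concatenate([np.asarray(m).reshape(-1) for m in maps])


def per_class_dice(pred, target, n_classes: int, per_image: bool = False) -> DiceResult:
    """Per-class Dice ``2|P∩T| / (|P|+|T|)``.

    ``pred`` and ``target`` are index maps (arrays or lists of arrays,
    argmax already applied).  By default intersection and size counts are
    pooled over the whole evaluation set before dividing; with
    ``per_image=True`` Dice is computed per map and averaged.
    """
    if per_image:
        results = [
            per_class_dice(p, t, n_classes).per_class
            for p, t in zip(pred, target)
        ]
        stack = np.stack(results)
        pc = stack.mean(axis=0)
        # supports/absence still reported set-wide
        pooled = per_class_dice(pred, target, n_classes)
        return DiceResult(pc, pooled.support_pred, pooled.support_target, pooled.absent)
    p = _stack_maps(pred)
    t = _stack_maps(target)
    if p.shape != t.shape:
        raise DimensionError(f"pred ({p.shape}) and target ({t.shape}) sizes differ")
    if p.size and (p.max() >= n_classes or t.max() >= n_classes):
        raise DataError(
            f"n_classes={n_classes} smaller than max index "
            f"{int(max(p.max(), t.max()))}"
        )
    sup_p = np.bincount(p, minlength=n_classes)[:n_classes]
    sup_t = np.bincount(t, minlength=n_classes)[:n_classes]
    inter = np.bincount(p[p == t], minlength=n_classes)[:n_classes]
    denom = sup_p + sup_t
    absent = denom == 0
    dice = np.where(absent, 1.0, 2.0 * inter / np.maximum(denom, 1))
    return DiceResult(dice, sup_p, sup_t, absent)


def mean_dice(pred, target, n_classes: int, per_image: bool = False) -> float:
    """Mean over classes of :func:`per_class_dice`."""
    return per_class_dice(pred, target, n_classes, per_image=per_image).mean
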