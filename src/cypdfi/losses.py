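"""Training objectives.

The primary objective is mean binary cross-entropy on the pairwise
interaction labels.  The auxiliary objective regularizes the attention of
the two supervised heads: a compound's predicted substrate/inhibition score
for an isoenzyme is the attention mass placed on its *real* substructures,
and that score is pushed toward the annotated label by binary cross-entropy
— but only where an annotation exists.  Compounds (typically all food
compounds) without annotations contribute nothing, leaving their attention
unsupervised.  The composite objective is ``L = L1 + alpha * L2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cyp import INTERACTION_TYPES, ISOENZYMES
from .nn import Tensor

EPS = 1e-7

__all__ = ["DciLabelMatrix", "BatchLosses", "primary_loss", "auxiliary_loss", "total_loss", "EPS"]


@dataclass(frozen=True)
class DciLabelMatrix:
    """Three-valued 2x5 label grid: rows (substrate, inhibition), columns the
    canonical isoenzyme order; entries 1.0 (positive), 0.0 (negative) or NaN
    (missing).  A fully-NaN matrix is the normal state for food compounds."""

    values: np.ndarray  # (2, 5) float with NaN for missing

    def __post_init__(self):
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.shape != (len(INTERACTION_TYPES), len(ISOENZYMES)):
            raise ValueError(f"label matrix must be {(2, len(ISOENZYMES))}, got {arr.shape}")
        finite = arr[np.isfinite(arr)]
        if not np.all(np.isin(finite, (0.0, 1.0))):
            raise ValueError("labels must be 0, 1 or NaN")
        object.__setattr__(self, "values", arr)

    @classmethod
    def missing(cls) -> "DciLabelMatrix":
        return cls(np.full((2, len(ISOENZYMES)), np.nan))

    @property
    def n_labeled(self) -> int:
        return int(np.isfinite(self.values).sum())


@dataclass(frozen=True)
class BatchLosses:
    l1: float
    l2: float
    total: float
    n_supervised: int


def primary_loss(y_hat: Tensor, y: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over the batch of pair predictions."""
    y = np.asarray(y, dtype=np.float64).reshape(-1)
    if y_hat.data.reshape(-1).shape != y.shape:
        raise ValueError(f"length mismatch: {y_hat.shape} predictions vs {y.shape} labels")
    if y.size == 0:
        raise ValueError("empty batch")
    p = y_hat.reshape(-1).clip(EPS, 1.0 - EPS)
    yl = Tensor(y)
    return -(yl * p.log() + (1.0 - yl) * (1.0 - p).log()).mean()


def auxiliary_loss(scores: Tensor, labels: np.ndarray) -> tuple[Tensor, int]:
    """Masked BCE of attention-mass DCI scores against annotations.

    ``scores``: (B, 2, 5) attention mass on real substructures for heads
    (substrate, inhibition); ``labels``: same shape with NaN marking missing
    annotations.  The loss is a flat mean over all non-missing cells in the
    batch; with no labeled cell it is exactly 0 with no gradient.
    """
    labels = np.asarray(labels, dtype=np.float64)
    if labels.shape != scores.data.shape:
        raise ValueError(f"shape mismatch: scores {scores.shape} vs labels {labels.shape}")
    observed = np.isfinite(labels)
    n_sup = int(observed.sum())
    if n_sup == 0:
        return Tensor(0.0), 0
    idx = np.nonzero(observed)
    p = scores[idx].clip(EPS, 1.0 - EPS)
    yl = Tensor(labels[idx])
    loss = -(yl * p.log() + (1.0 - yl) * (1.0 - p).log()).mean()
    return loss, n_sup


def total_loss(l1: Tensor, l2: Tensor, alpha: float) -> Tensor:
    """Composite objective ``L1 + alpha * L2``."""
    return l1 + alpha * l2
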