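"""Class-weighted categorical cross-entropy and deep supervision.

The per-voxel cross-entropy of the softmax-normalized scores against the
true class is combined as a weighted *mean*,

    L = sum_i w_i * ce_i / sum_i w_i,

where ``w_i`` is the weight of voxel i's true class (kidney 5, background 1
by default). Normalizing by the total weight keeps the loss magnitude
independent of patch size. Deep supervision evaluates the same loss at
every decoder scale against nearest-neighbor-downsampled labels and
combines the scales by a normalized weighted sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ContractError, DataError

__all__ = ["ClassWeights", "weighted_ce", "weighted_ce_grad", "deep_supervision_loss",
           "deep_supervision_grad", "default_scale_weights", "downsample_labels"]


@dataclass(frozen=True)
class ClassWeights:
    """Loss weights per true class (background, left kidney, right kidney)."""

    background: float = 1.0
    left_kidney: float = 5.0
    right_kidney: float = 5.0

    def __post_init__(self):
        if min(self.background, self.left_kidney, self.right_kidney) <= 0:
            raise ContractError("class weights must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.background, self.left_kidney, self.right_kidney], dtype=np.float64)


def _as_batch(scores: np.ndarray, labels: np.ndarray):
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    if labels.ndim == 3:  # unbatched (3, d, h, w) / (d, h, w)
        scores = scores[None]
        labels = labels[None]
    elif labels.ndim != 4:
        raise ContractError(f"labels must be 3D or batched 4D, got shape {labels.shape}")
    if scores.shape[0] != labels.shape[0] or scores.shape[2:] != labels.shape[1:]:
        raise ContractError(
            f"scores {scores.shape} and labels {labels.shape} are not spatially aligned"
        )
    if scores.shape[1] != 3:
        raise ContractError(f"expected 3 score channels, got {scores.shape[1]}")
    if labels.dtype.kind not in "iu" or labels.min() < 0 or labels.max() > 2:
        raise DataError("labels must be integers in {0, 1, 2}")
    return scores.astype(np.float64), labels


def weighted_ce_grad(scores, labels, weights: ClassWeights = ClassWeights()):
    """Weighted-mean softmax cross-entropy and its gradient w.r.t. the scores.

    Returns ``(loss, dscores)`` where dscores has the batched score shape
    and already includes the 1/sum(w) normalization.
    """
    s, y = _as_batch(scores, labels)
    s = s - s.max(axis=1, keepdims=True)
    logz = np.log(np.exp(s).sum(axis=1, keepdims=True))
    logp = s - logz  # (N, 3, spatial)
    w = weights.as_array()[y]  # (N, spatial)
    wsum = w.sum()
    logp_true = np.take_along_axis(logp, y[:, None], axis=1)[:, 0]
    loss = float(-(w * logp_true).sum() / wsum)
    p = np.exp(logp)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, y[:, None], 1.0, axis=1)
    dscores = (p - onehot) * w[:, None] / wsum
    return loss, dscores


def weighted_ce(scores, labels, weights: ClassWeights = ClassWeights()) -> float:
    """Scalar weighted-mean cross-entropy (see :func:`weighted_ce_grad`)."""
    return weighted_ce_grad(scores, labels, weights)[0]


def downsample_labels(labels: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbor label downsampling by an integer factor per axis."""
    if factor == 1:
        return labels
    sl = (slice(None),) * (labels.ndim - 3) + (slice(None, None, factor),) * 3
    return labels[sl]


def default_scale_weights(n_scales: int) -> list[float]:
    """Halving weights 1, 1/2, 1/4, ... (finest scale first)."""
    return [0.5**s for s in range(n_scales)]


def deep_supervision_grad(
    per_scale_scores, labels, weights: ClassWeights = ClassWeights(), scale_weights=None
):
    """Deep-supervision loss and per-scale score gradients.

    ``per_scale_scores[s]`` is the score map at scale s (finest first, each
    coarser by 2x); labels are downsampled to each scale by nearest neighbor.
    Total loss is sum_s sw[s] * L_s / sum_s sw[s].
    """
    if scale_weights is None:
        scale_weights = default_scale_weights(len(per_scale_scores))
    if len(scale_weights) != len(per_scale_scores):
        raise ContractError(
            f"{len(per_scale_scores)} score maps but {len(scale_weights)} scale weights"
        )
    if any(sw <= 0 for sw in scale_weights):
        raise ContractError("scale weights must be positive")
    swsum = float(sum(scale_weights))
    total = 0.0
    grads = []
    for s, (scores, sw) in enumerate(zip(per_scale_scores, scale_weights)):
        lab_s = downsample_labels(labels, 2**s)
        loss_s, grad_s = weighted_ce_grad(scores, lab_s, weights)
        total += sw * loss_s / swsum
        grads.append(grad_s * (sw / swsum))
    return total, grads


def deep_supervision_loss(
    per_scale_scores, labels, weights: ClassWeights = ClassWeights(), scale_weights=None
) -> float:
    """Scalar deep-supervision loss (see :func:`deep_supervision_grad`)."""
    return deep_supervision_grad(per_scale_scores, labels, weights, scale_weights)[0]
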