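"""Per-frame unsupervised semantic segmentation.

Training alternates two processes on a single frame: (1) predict per-pixel
cluster labels with the current network (argmax over the 4 softmax maps,
then majority refinement within each superpixel), and (2) update the
network by stochastic gradient descent toward those refined labels under
the improved loss

    L = L_ce + alpha * L_fs,      L_fs = |Fs - C|

where L_ce is the pixelwise cross-entropy against the refined labels and
L_fs penalizes the distance between the shape factor of the corneal-
candidate region and the cornea-specific constant C (default 10).

Fs is computed from hard argmax labels and is piecewise constant, so L_fs
carries no gradient by default; it still shapes training through the
early-stopping criterion.  An optional differentiable surrogate (soft area
= summed candidate-channel probability, soft perimeter = its total
variation) can be enabled with ``TrainConfig.shape_factor_gradient``.
"""
from __future__ import annotations

import logging
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .config import TrainConfig
from .network import (
    N_CLASSES,
    NetworkState,
    SGDMomentum,
    backward,
    forward,
    init_network,
)
from .region import shape_factor
from .superpixel import SuperpixelPartition

__all__ = [
    "assign_labels",
    "refine_labels",
    "cross_entropy_loss",
    "shape_factor_loss",
    "total_loss",
    "train_frame",
    "DegenerateSegmentationError",
]

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)


class DegenerateSegmentationError(RuntimeError):
    """Training collapsed to a single label and retries were exhausted."""


def assign_labels(fm: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over the q class-score maps (ties -> lowest index)."""
    return np.argmax(fm, axis=-1).astype(np.int32)


def refine_labels(lm: np.ndarray, part: SuperpixelPartition) -> np.ndarray:
    """Replace every pixel's label by its superpixel's modal label.

    Ties break toward the lowest label value.  Idempotent: a map that is
    already constant within each superpixel is returned unchanged.
    """
    lm = np.asarray(lm)
    if lm.shape != part.labels.shape:
        raise ValueError(
            f"label map shape {lm.shape} != partition shape {part.labels.shape}"
        )
    idx = part.labels.ravel().astype(np.int64) * N_CLASSES + lm.ravel()
    counts = np.bincount(idx, minlength=part.K * N_CLASSES).reshape(
        part.K, N_CLASSES
    )
    modal = counts.argmax(axis=1).astype(lm.dtype)
    return modal[part.labels]


def cross_entropy_loss(fm: np.ndarray, target: np.ndarray) -> float:
    """Mean over pixels of -log(softmax score of the target label)."""
    fm = np.asarray(fm)
    target = np.asarray(target)
    if fm.shape[:-1] != target.shape:
        raise ValueError(f"shape mismatch: {fm.shape[:-1]} vs {target.shape}")
    h, w = target.shape
    p = fm.reshape(-1, fm.shape[-1])[np.arange(h * w), target.ravel()]
    return float(-np.log(np.maximum(p, 1e-12)).mean())


def _largest_component(mask: np.ndarray) -> Optional[np.ndarray]:
    comp, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return None
    sizes = np.bincount(comp.ravel())[1:]
    return comp == (int(np.argmax(sizes)) + 1)


def candidate_label(lm: np.ndarray, shape_target: float) -> Tuple[int, float]:
    """Label whose largest connected region has Fs closest to the target.

    Returns ``(label, Fs)`` of the corneal-candidate region.
    """
    best: Optional[Tuple[int, float]] = None
    for lab in np.unique(lm):
        largest = _largest_component(lm == lab)
        if largest is None:
            continue
        fs = shape_factor(largest)
        if best is None or abs(fs - shape_target) < abs(best[1] - shape_target):
            best = (int(lab), fs)
    return best


def shape_factor_loss(lm: np.ndarray, shape_target: float = 10.0) -> float:
    """|Fs - C| of the corneal-candidate region of a label map.

    Translation invariant (Fs depends only on the region's geometry).  For
    a degenerate map with a single label covering everything, the full
    frame is the candidate and the degeneracy is logged.
    """
    lm = np.asarray(lm)
    if lm.size == 0:
        raise ValueError("label map is empty")
    labels = np.unique(lm)
    if labels.size == 1:
        logger.debug("degenerate segmentation: single label %d", labels[0])
    _, fs = candidate_label(lm, shape_target)
    return abs(fs - shape_target)


def total_loss(
    fm: np.ndarray, target: np.ndarray, lm: np.ndarray, cfg: TrainConfig
) -> float:
    """Improved loss L = L_ce(fm, target) + alpha * |Fs(lm) - C|."""
    loss = cross_entropy_loss(fm, target)
    if cfg.alpha > 0:
        loss += cfg.alpha * shape_factor_loss(lm, cfg.shape_target)
    return loss


def _soft_shape_loss_grad(
    probs: np.ndarray, channel: int, shape_target: float
) -> Tuple[float, np.ndarray]:
    """Differentiable |Fs - C| surrogate on one softmax channel.

    Soft area A = sum(p), soft perimeter P = total variation of p, soft
    Fs = P**2 / (4*pi*A).  Returns the loss value and its gradient with
    respect to the full probability tensor.
    """
    p = probs[..., channel].astype(np.float64)
    dx = np.diff(p, axis=1)
    dy = np.diff(p, axis=0)
    P = float(np.abs(dx).sum() + np.abs(dy).sum())
    A = float(p.sum())
    fs = P**2 / (4.0 * np.pi * max(A, 1e-8))
    sign = np.sign(fs - shape_target)
    # dP/dp via TV subgradient
    dP = np.zeros_like(p)
    sx = np.sign(dx)
    dP[:, 1:] += sx
    dP[:, :-1] -= sx
    sy = np.sign(dy)
    dP[1:, :] += sy
    dP[:-1, :] -= sy
    dfs = (2.0 * P * dP * A - P**2) / (4.0 * np.pi * A**2)
    grad = np.zeros_like(probs, dtype=np.float64)
    grad[..., channel] = sign * dfs
    return abs(fs - shape_target), grad


def train_frame(
    frame: np.ndarray,
    part: SuperpixelPartition,
    init: NetworkState,
    cfg: TrainConfig,
    max_epochs: Optional[int] = None,
    cold_retry_seed: Optional[int] = None,
) -> Tuple[NetworkState, np.ndarray, List[float]]:
    """Train the FCN on one frame; returns (state, refined labels, losses).

    Each epoch: forward -> argmax labels -> superpixel majority refinement
    -> improved loss against the refined labels -> SGD step.  Stops at
    ``max_epochs`` (default ``cfg.max_epochs_first_frame``), when the loss
    first drops below ``cfg.loss_stop_threshold``, or when the number of
    distinct refined labels falls below ``cfg.min_labels``.

    With ``cold_retry_seed`` set (cold starts only), a run that collapses to
    a single label is restarted from a fresh seed up to 3 times before
    :class:`DegenerateSegmentationError` is raised.
    """
    if max_epochs is None:
        max_epochs = cfg.max_epochs_first_frame
    frame = np.asarray(frame)
    if frame.ndim == 2:
        frame = np.repeat(frame[..., None], 3, axis=-1)
    if frame.shape[:2] != part.labels.shape:
        raise ValueError(
            f"frame shape {frame.shape[:2]} != partition shape {part.labels.shape}"
        )

    retries = 3 if cold_retry_seed is not None else 0
    attempt = 0
    state = init.copy()
    while True:
        result = _train_once(frame, part, state, cfg, max_epochs)
        if result is not None:
            return result
        attempt += 1
        if attempt > retries:
            raise DegenerateSegmentationError(
                "segmentation collapsed to a single label"
            )
        logger.debug("collapse on cold start; re-initializing (attempt %d)", attempt)
        state = init_network(cfg, seed=cold_retry_seed + 7919 * attempt)


def _train_once(frame, part, state, cfg, max_epochs):
    opt = SGDMomentum(state, lr=cfg.lr, momentum=cfg.momentum)
    history: List[float] = []
    refined = None
    h, w = frame.shape[:2]
    n_pix = h * w
    for _epoch in range(max_epochs):
        probs, caches = forward(state, frame, train=True, return_cache=True)
        lm = assign_labels(probs)
        refined = refine_labels(lm, part)
        n_labels = int(np.unique(refined).size)
        loss_ce = cross_entropy_loss(probs, refined)
        loss = loss_ce
        shape_grad = None
        if cfg.alpha > 0:
            if cfg.shape_factor_gradient:
                chan, _ = candidate_label(refined, cfg.shape_target)
                l_fs, shape_grad = _soft_shape_loss_grad(
                    probs, chan, cfg.shape_target
                )
            else:
                l_fs = shape_factor_loss(refined, cfg.shape_target)
            loss = loss_ce + cfg.alpha * l_fs
        history.append(float(loss))
        logger.debug("epoch %d: loss %.4f (%d labels)", _epoch, loss, n_labels)
        if n_labels < 2:
            return None  # full collapse; wrapper retries (cold) or raises
        if loss < cfg.loss_stop_threshold:
            break
        if n_labels < cfg.min_labels:
            break
        # gradient of the mean cross-entropy w.r.t. the C6 logits
        dlogits = probs.copy()
        flat = dlogits.reshape(n_pix, -1)
        flat[np.arange(n_pix), refined.ravel()] -= 1.0
        dlogits /= n_pix
        if shape_grad is not None:
            # chain the soft shape term through the softmax
            extra = cfg.alpha * shape_grad
            dot = (extra * probs).sum(axis=-1, keepdims=True)
            dlogits += (probs * (extra - dot)).astype(dlogits.dtype)
        grads = backward(state, caches, dlogits)
        opt.step(state, grads)
    return state, refined, history
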