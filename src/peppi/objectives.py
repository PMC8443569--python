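"""Dual-objective losses and decision thresholds.

The pair task uses mean binary cross-entropy over pairs; the residue task
uses a masked cross-entropy normalized per sample by its number of real
residues M_i, then averaged over samples. The two are combined as
loss_total = loss_pair + lambda * loss_pep.
"""

from __future__ import annotations

import logging

import numpy as np

from .exceptions import InvalidInputError

logger = logging.getLogger(__name__)

#: Probabilities are clipped to [EPS, 1 - EPS] before logs.
EPS = 1e-7


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS, 1.0 - EPS)


def pair_loss(labels: np.ndarray, probs: np.ndarray) -> float:
    """Mean binary cross-entropy over peptide-protein pairs."""
    labels = np.asarray(labels, dtype=np.float64)
    probs = np.asarray(probs, dtype=np.float64)
    if labels.shape != probs.shape:
        raise InvalidInputError(f"shape mismatch: {labels.shape} vs {probs.shape}")
    p = _clip(probs)
    return float(-np.mean(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)))


def residue_loss(labels: np.ndarray, probs: np.ndarray, masks: np.ndarray) -> float:
    """Masked cross-entropy for residue labels.

    Each sample's cross-entropy is averaged over its own M_i unmasked
    positions; the result is the mean over samples. Samples with no real
    positions contribute zero (logged).
    """
    labels = np.atleast_2d(np.asarray(labels, dtype=np.float64))
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    masks = np.atleast_2d(np.asarray(masks, dtype=np.float64))
    if not labels.shape == probs.shape == masks.shape:
        raise InvalidInputError(
            f"shape mismatch: {labels.shape}, {probs.shape}, {masks.shape}"
        )
    p = _clip(probs)
    ce = -(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)) * masks
    M = masks.sum(axis=1)
    empty = M == 0
    if np.any(empty):
        logger.debug("%d samples have no unmasked residue positions", int(empty.sum()))
    per_sample = np.where(empty, 0.0, ce.sum(axis=1) / np.maximum(M, 1.0))
    return float(per_sample.mean())


def total_loss(lp: float, lr: float, lam: float) -> float:
    """loss_total = loss_pair + lambda * loss_pep."""
    if lam < 0:
        raise InvalidInputError("lambda must be non-negative")
    return lp + lam * lr


def classify_pair(prob: float | np.ndarray) -> np.ndarray | int:
    """1 iff interaction probability >= 0.5 (boundary inclusive)."""
    arr = np.asarray(prob, dtype=np.float64)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise InvalidInputError("probability outside [0, 1]")
    out = (arr >= 0.5).astype(np.int64)
    return int(out) if out.ndim == 0 else out


def classify_residue(prob: float | np.ndarray) -> np.ndarray | int:
    """1 iff residue binding probability >= 0.5 (boundary inclusive)."""
    return classify_pair(prob)


def loss_gradients(
    pair_labels: np.ndarray,
    pair_probs: np.ndarray,
    res_labels: np.ndarray,
    res_probs: np.ndarray,
    res_masks: np.ndarray,
    lam: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of total_loss w.r.t. the two heads' pre-sigmoid logits.

    For clipped sigmoid + cross-entropy the logit gradient is (p - y) scaled
    by the loss normalization; positions outside the clip range contribute
    the clipped-probability gradient, which is numerically negligible and
    treated as (p - y) here.
    """
    N = len(pair_labels)
    dlogit_pair = (pair_probs - pair_labels) / N
    M = res_masks.sum(axis=1)
    scale = lam / (N * np.maximum(M, 1.0))
    dlogit_res = (res_probs - res_labels) * res_masks * scale[:, None]
    return dlogit_pair, dlogit_res
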