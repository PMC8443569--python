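"""Seeded multi-objective training loop with an RMSProp optimizer.

Both heads are optimized simultaneously: every minibatch step computes the
pair cross-entropy and the masked residue cross-entropy, combines them as
loss_pair + lambda * loss_pep, backpropagates through the shared trunk and
updates all parameters with RMSProp. All stochasticity (initialization,
shuffling, dropout) is driven by the single config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError
from .network import (
    ArchitectureConfig,
    ModelParams,
    PairSample,
    ProfileBatch,
    backward_batch,
    forward_batch,
    init_params,
    zero_grads,
)
from .objectives import loss_gradients, pair_loss, residue_loss, total_loss

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization hyperparameters. ``seed`` fixes all stochasticity."""

    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 64
    lam: float = 0.1  # weight of the residue loss in the total objective
    rmsprop_decay: float = 0.9
    rmsprop_eps: float = 1e-8
    seed: int = 0
    dropout: float | None = None  # overrides the architecture's rate if set
    weight_decay: float = 0.0  # decoupled L2 shrinkage per step
    dtype: str = "float32"  # float32 is ample for SGD; checks use float64

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise InvalidInputError("lambda must be non-negative")
        if self.epochs < 1 or self.batch_size < 1:
            raise InvalidInputError("epochs and batch size must be positive")


@dataclass
class LossReport:
    """Per-epoch average losses; loss_total = loss_pair + lambda * loss_pep."""

    epoch: int
    loss_pair: float
    loss_pep: float
    loss_total: float


@dataclass
class TrainingState:
    params: ModelParams
    history: list[LossReport] = field(default_factory=list)


class RMSProp:
    """Adaptive-gradient optimizer: running mean of squared gradients.

    Weight decay is decoupled (applied directly to the weights, not through
    the adaptive denominator)."""

    def __init__(
        self,
        params: ModelParams,
        lr: float,
        decay: float,
        eps: float,
        weight_decay: float = 0.0,
    ):
        self.lr = lr
        self.decay = decay
        self.eps = eps
        self.weight_decay = weight_decay
        self.cache = {k: np.zeros_like(v) for k, v in params.arrays.items()}

    def step(self, params: ModelParams, grads: dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            c = self.cache[k]
            c *= self.decay
            c += (1.0 - self.decay) * g * g
            params.arrays[k] -= self.lr * g / (np.sqrt(c) + self.eps)
            if self.weight_decay and not k.endswith("_b") and k != "res_c":
                params.arrays[k] -= self.lr * self.weight_decay * params.arrays[k]
        # keep padding embedding rows frozen at zero
        for k in params.arrays:
            if "_emb_" in k:
                params.arrays[k][0] = 0.0


@dataclass
class StackedDataset:
    """Whole-dataset profile stacks plus label arrays, sliceable per minibatch."""

    pep: ProfileBatch
    pro: ProfileBatch
    pair_labels: np.ndarray  # (N,)
    res_labels: np.ndarray  # (N, L_pep)
    res_masks: np.ndarray  # (N, L_pep); peptide mask zeroed where labels absent

    @classmethod
    def from_samples(cls, samples: list[PairSample]) -> "StackedDataset":
        if not samples:
            raise InvalidInputError("empty dataset")
        pep = ProfileBatch.from_profiles([s.peptide for s in samples])
        pro = ProfileBatch.from_profiles([s.protein for s in samples])
        N, L = pep.mask.shape
        labels = np.array([s.label for s in samples], dtype=np.float64)
        res_labels = np.zeros((N, L))
        res_masks = np.zeros((N, L))
        for i, s in enumerate(samples):
            if s.binding_vector is not None:
                bv = np.asarray(s.binding_vector, dtype=np.float64)
                res_labels[i, : len(bv)] = bv
                res_masks[i] = pep.mask[i]
        return cls(pep, pro, labels, res_labels, res_masks)

    def __len__(self) -> int:
        return len(self.pair_labels)


def train(
    dataset: list[PairSample] | StackedDataset,
    arch: ArchitectureConfig,
    cfg: TrainConfig,
    init: ModelParams | None = None,
    callback=None,
) -> TrainingState:
    """Train from scratch (or from ``init``) and return params + loss history."""
    data = dataset if isinstance(dataset, StackedDataset) else StackedDataset.from_samples(dataset)
    labels = data.pair_labels
    if len(data) == 0 or labels.min() == labels.max():
        raise InvalidInputError("dataset needs at least one positive and one negative pair")

    if cfg.dropout is not None and cfg.dropout != arch.dropout:
        arch = ArchitectureConfig(**{**arch.to_dict(), "dropout": cfg.dropout})
    params = init.copy() if init is not None else init_params(arch, seed=cfg.seed)
    params = params.astype(np.dtype(cfg.dtype))
    opt = RMSProp(
        params, cfg.learning_rate, cfg.rmsprop_decay, cfg.rmsprop_eps,
        weight_decay=cfg.weight_decay,
    )
    rng = np.random.default_rng(cfg.seed + 1)
    state = TrainingState(params=params)

    N = len(data)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(N)
        lp_sum = lr_sum = 0.0
        n_batches = 0
        for start in range(0, N, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            pep = data.pep.take(idx)
            pro = data.pro.take(idx)
            y = labels[idx]
            bl = data.res_labels[idx]
            bm = data.res_masks[idx]

            out, caches = forward_batch(pep, pro, params, mode="train", dropout_rng=rng)
            lp = pair_loss(y, out["pair_probs"])
            lr_ = residue_loss(bl, out["residue_probs"], bm)
            lt = total_loss(lp, lr_, cfg.lam)
            if not np.isfinite(lt):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: pair={lp}, pep={lr_}"
                )
            dlogit_pair, dlogit_res = loss_gradients(
                y, out["pair_probs"], bl, out["residue_probs"], bm, cfg.lam
            )
            dlogit_pair = dlogit_pair.astype(params.dtype, copy=False)
            dlogit_res = dlogit_res.astype(params.dtype, copy=False)
            grads = zero_grads(params)
            backward_batch(dlogit_pair, dlogit_res, caches, params, grads)
            opt.step(params, grads)

            lp_sum += lp
            lr_sum += lr_
            n_batches += 1

        report = LossReport(
            epoch=epoch,
            loss_pair=lp_sum / n_batches,
            loss_pep=lr_sum / n_batches,
            loss_total=total_loss(lp_sum / n_batches, lr_sum / n_batches, cfg.lam),
        )
        state.history.append(report)
        logger.info(
            "epoch %d: loss_pair=%.4f loss_pep=%.4f loss_total=%.4f",
            epoch, report.loss_pair, report.loss_pep, report.loss_total,
        )
        if callback is not None:
            callback(epoch, state)
    return state


def gradient_check(
    data: StackedDataset,
    arch: ArchitectureConfig,
    lam: float = 0.3,
    seed: int = 0,
    n_probes_per_array: int = 5,
    eps: float = 1e-5,
    jitter: float = 0.05,
) -> float:
    """Max relative error between backprop and central finite differences.

    Parameters are jittered away from their initialization so no ReLU
    pre-activation sits exactly on its kink (padded inputs with zero biases
    otherwise do, where the subgradient convention ReLU'(0)=0 and a central
    difference legitimately disagree).
    """
    params = init_params(arch, seed=seed)
    rng = np.random.default_rng(seed + 1)
    for k, v in params.arrays.items():
        v += rng.normal(scale=jitter, size=v.shape)
        if "_emb_" in k:
            v[0] = 0.0

    def loss_of() -> float:
        out, _ = forward_batch(data.pep, data.pro, params, mode="eval")
        lp = pair_loss(data.pair_labels, out["pair_probs"])
        lr_ = residue_loss(data.res_labels, out["residue_probs"], data.res_masks)
        return total_loss(lp, lr_, lam)

    out, caches = forward_batch(data.pep, data.pro, params, mode="eval")
    dlp, dlr = loss_gradients(
        data.pair_labels, out["pair_probs"], data.res_labels,
        out["residue_probs"], data.res_masks, lam,
    )
    grads = zero_grads(params)
    backward_batch(dlp, dlr, caches, params, grads)

    worst = 0.0
    for name in sorted(params.arrays):
        arr = params.arrays[name]
        for _ in range(n_probes_per_array):
            if arr.ndim:
                idx = tuple(int(rng.integers(s)) for s in arr.shape)
                if "_emb_" in name and idx[0] == 0:
                    continue  # frozen padding row carries no gradient
                orig = arr[idx]
                arr[idx] = orig + eps
                l1 = loss_of()
                arr[idx] = orig - eps
                l2 = loss_of()
                arr[idx] = orig
                ana = grads[name][idx]
            else:
                orig = float(arr)
                params.arrays[name] = np.array(orig + eps)
                l1 = loss_of()
                params.arrays[name] = np.array(orig - eps)
                l2 = loss_of()
                params.arrays[name] = np.array(orig)
                arr = params.arrays[name]
                ana = float(grads[name])
            num = (l1 - l2) / (2.0 * eps)
            if max(abs(num), abs(ana)) < 1e-8:
                continue
            worst = max(worst, abs(num - ana) / max(abs(num), abs(ana)))
    return worst


def predict_batch(
    data: StackedDataset, params: ModelParams, batch_size: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic eval-mode predictions: (pair probs (N,), residue probs (N, L))."""
    probs = []
    res = []
    for start in range(0, len(data), batch_size):
        idx = np.arange(start, min(start + batch_size, len(data)))
        out, _ = forward_batch(data.pep.take(idx), data.pro.take(idx), params, mode="eval")
        probs.append(out["pair_probs"])
        res.append(out["residue_probs"])
    return np.concatenate(probs), np.concatenate(res)
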