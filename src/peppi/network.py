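"""Multi-channel CNN + single-head self-attention network for peptide-protein pairs.

The model embeds each sequence through four channels (three learned
categorical embeddings — amino acid, secondary-structure combination,
polarity/hydropathy combination — plus an affine map of the dense numeric
features), then runs two parallel feature extractors per chain:

* a 3-layer same-padding 1-D convolution stack with ReLU, reduced by a
  masked global max pool, and
* scaled dot-product self-attention over the embedding output, reduced by a
  masked mean pool.

The four pooled vectors (peptide CNN, protein CNN, peptide attention,
protein attention) feed a 3-layer fully connected binary head with dropout
and a sigmoid output; the peptide's pre-pooling convolution features feed a
per-position single-layer residue head sigma(W_pep . h_j + c).

Everything is NumPy; gradients are hand-written reverse-mode passes
(`backward_batch`) verified against finite differences in the test suite.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .exceptions import ConfigurationError, InvalidInputError
from .featurization import (
    N_POLHYD_CODES,
    N_SS_CODES,
    FeatureProfile,
    Role,
    numeric_dim,
)

Mode = Literal["train", "eval"]


@dataclass(frozen=True)
class ArchitectureConfig:
    """All architecture hyperparameters. Defaults are a small CPU-friendly profile."""

    embed_dim: int = 16
    conv_filters: tuple[int, int, int] = (64, 64, 128)
    conv_kernels: tuple[int, int, int] = (7, 5, 3)
    attention_dim: int = 32
    fc_sizes: tuple[int, int] = (256, 128)
    dropout: float = 0.2

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 3 or len(self.conv_kernels) != 3:
            raise ConfigurationError("exactly three convolution layers are required")
        if len(self.fc_sizes) != 2:
            raise ConfigurationError("binary head has three FC layers (two hidden sizes)")
        dims = (self.embed_dim, self.attention_dim, *self.conv_filters, *self.fc_sizes)
        if any(d <= 0 for d in dims) or any(k <= 0 for k in self.conv_kernels):
            raise ConfigurationError("all dimensions must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError("dropout must be in [0, 1)")

    @property
    def channel_dim(self) -> int:
        """Width of the concatenated embedding: 3 categorical + 1 numeric channel."""
        return 4 * self.embed_dim

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("conv_filters", "conv_kernels", "fc_sizes"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        d = dict(d)
        for k in ("conv_filters", "conv_kernels", "fc_sizes"):
            d[k] = tuple(d[k])
        return cls(**d)


#: Desk-scale preset used for synthetic-data training runs.
TINY_ARCH = ArchitectureConfig(
    embed_dim=8,
    conv_filters=(16, 16, 32),
    conv_kernels=(7, 5, 3),
    attention_dim=8,
    fc_sizes=(64, 32),
    dropout=0.2,
)


@dataclass
class AttentionWeights:
    """Query/key/value projections of single-head self-attention."""

    W_q: np.ndarray
    W_k: np.ndarray
    W_v: np.ndarray

    @property
    def d_k(self) -> int:
        return self.W_q.shape[0]

    @property
    def scale(self) -> float:
        return float(np.sqrt(self.d_k))


@dataclass
class ResidueHeadWeights:
    """Single-layer residue head: per-position logit W_pep . h_j + c."""

    W_pep: np.ndarray  # (C,)
    c: float  # shared position-independent bias


@dataclass
class PairSample:
    """One peptide/protein pair with its label and optional residue labels."""

    peptide: FeatureProfile
    protein: FeatureProfile
    label: int
    binding_vector: np.ndarray | None = None  # length = peptide pad length, padded 0

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise InvalidInputError(f"label must be 0/1, got {self.label}")


_EMB_TABLES = {"aa": 22, "ss": N_SS_CODES + 1, "ph": N_POLHYD_CODES + 1}


@dataclass
class ModelParams:
    """All learnable arrays, keyed by name, plus the architecture they realize."""

    arch: ArchitectureConfig
    arrays: dict[str, np.ndarray] = field(default_factory=dict)

    def attention_weights(self, role: Role) -> AttentionWeights:
        p = "pep" if role == "peptide" else "pro"
        return AttentionWeights(
            self.arrays[f"{p}_Wq"], self.arrays[f"{p}_Wk"], self.arrays[f"{p}_Wv"]
        )

    def residue_head(self) -> ResidueHeadWeights:
        return ResidueHeadWeights(self.arrays["res_W"], float(self.arrays["res_c"]))

    def copy(self) -> "ModelParams":
        return ModelParams(self.arch, {k: v.copy() for k, v in self.arrays.items()})

    def astype(self, dtype) -> "ModelParams":
        return ModelParams(self.arch, {k: v.astype(dtype) for k, v in self.arrays.items()})

    @property
    def dtype(self):
        return self.arrays["fc1_W"].dtype

    def n_parameters(self) -> int:
        return sum(int(v.size) for v in self.arrays.values())


def init_params(arch: ArchitectureConfig, seed: int = 0) -> ModelParams:
    """He/Glorot-style initialization; embedding row 0 frozen to zero."""
    rng = np.random.default_rng(seed)
    arrays: dict[str, np.ndarray] = {}

    def glorot(shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape)

    d = arch.embed_dim
    D = arch.channel_dim
    for role, p in (("peptide", "pep"), ("protein", "pro")):
        for name, rows in _EMB_TABLES.items():
            table = rng.normal(0.0, 0.1, size=(rows, d))
            table[0] = 0.0
            arrays[f"{p}_emb_{name}"] = table
        dn = numeric_dim(role)
        arrays[f"{p}_num_W"] = glorot((dn, d), dn, d)
        arrays[f"{p}_num_b"] = np.zeros(d)
        c_in = D
        for i, (c_out, k) in enumerate(zip(arch.conv_filters, arch.conv_kernels), 1):
            arrays[f"{p}_conv{i}_W"] = glorot((c_out, k, c_in), k * c_in, c_out)
            arrays[f"{p}_conv{i}_b"] = np.zeros(c_out)
            c_in = c_out
        for w in ("Wq", "Wk", "Wv"):
            arrays[f"{p}_{w}"] = glorot((arch.attention_dim, D), D, arch.attention_dim)

    z_dim = 2 * arch.conv_filters[-1] + 2 * arch.attention_dim
    h1, h2 = arch.fc_sizes
    arrays["fc1_W"] = glorot((h1, z_dim), z_dim, h1)
    arrays["fc1_b"] = np.zeros(h1)
    arrays["fc2_W"] = glorot((h2, h1), h1, h2)
    arrays["fc2_b"] = np.zeros(h2)
    arrays["fc3_W"] = glorot((1, h2), h2, 1)
    arrays["fc3_b"] = np.zeros(1)
    arrays["res_W"] = glorot((arch.conv_filters[-1],), arch.conv_filters[-1], 1)
    arrays["res_c"] = np.zeros(())
    return ModelParams(arch, arrays)


# ---------------------------------------------------------------------------
# Batched profile container


@dataclass
class ProfileBatch:
    """Stacked profiles of one role, padded to a common length."""

    aa: np.ndarray  # (B, L) int
    ss: np.ndarray
    ph: np.ndarray
    numeric: np.ndarray  # (B, L, d_num)
    mask: np.ndarray  # (B, L) 0/1
    role: Role

    @classmethod
    def from_profiles(cls, profiles: list[FeatureProfile]) -> "ProfileBatch":
        role = profiles[0].role
        L = max(len(p.mask) for p in profiles)
        dn = profiles[0].numeric.shape[1]
        B = len(profiles)
        aa = np.zeros((B, L), dtype=np.int64)
        ss = np.zeros((B, L), dtype=np.int64)
        ph = np.zeros((B, L), dtype=np.int64)
        num = np.zeros((B, L, dn))
        mask = np.zeros((B, L), dtype=np.int64)
        for i, p in enumerate(profiles):
            n = len(p.mask)
            aa[i, :n] = p.aa_codes
            ss[i, :n] = p.ss_codes
            ph[i, :n] = p.polhyd_codes
            num[i, :n] = p.numeric
            mask[i, :n] = p.mask
        return cls(aa, ss, ph, num, mask, role)

    def take(self, idx: np.ndarray) -> "ProfileBatch":
        return ProfileBatch(
            self.aa[idx], self.ss[idx], self.ph[idx],
            self.numeric[idx], self.mask[idx], self.role,
        )

    def __len__(self) -> int:
        return self.aa.shape[0]


# ---------------------------------------------------------------------------
# Batched building blocks (forward + backward)


def _embed_forward(batch: ProfileBatch, params: ModelParams) -> tuple[np.ndarray, dict]:
    p = "pep" if batch.role == "peptide" else "pro"
    a = params.arrays
    numeric = batch.numeric.astype(params.dtype, copy=False)
    num_lin = numeric @ a[f"{p}_num_W"] + a[f"{p}_num_b"]
    U = np.concatenate(
        [
            a[f"{p}_emb_aa"][batch.aa],
            a[f"{p}_emb_ss"][batch.ss],
            a[f"{p}_emb_ph"][batch.ph],
            num_lin,
        ],
        axis=2,
    )
    U *= batch.mask[..., None]
    return U, {"batch": batch, "prefix": p}


def _embed_backward(dU: np.ndarray, cache: dict, grads: dict) -> None:
    batch: ProfileBatch = cache["batch"]
    p = cache["prefix"]
    dU = dU * batch.mask[..., None].astype(dU.dtype)
    d = dU.shape[2] // 4
    for i, (name, codes) in enumerate(
        [("aa", batch.aa), ("ss", batch.ss), ("ph", batch.ph)]
    ):
        g = grads[f"{p}_emb_{name}"]
        np.add.at(g, codes.ravel(), dU[:, :, i * d : (i + 1) * d].reshape(-1, d))
        g[0] = 0.0  # padding row stays frozen
    dnum = dU[:, :, 3 * d :]
    numeric = batch.numeric.astype(dU.dtype, copy=False)
    grads[f"{p}_num_W"] += np.tensordot(numeric, dnum, axes=([0, 1], [0, 1]))
    grads[f"{p}_num_b"] += dnum.sum(axis=(0, 1))


def _im2col(X: np.ndarray, k: int) -> np.ndarray:
    B, L, C = X.shape
    pad = k // 2
    Xp = np.pad(X, ((0, 0), (pad, pad), (0, 0)))
    s = Xp.strides
    win = as_strided(Xp, (B, L, k, C), (s[0], s[1], s[1], s[2]))
    return win.reshape(B, L, k * C)


def _conv_stack_forward(
    U: np.ndarray, params: ModelParams, prefix: str
) -> tuple[np.ndarray, dict]:
    arch = params.arch
    if U.shape[1] < max(arch.conv_kernels):
        raise InvalidInputError(
            f"sequence length {U.shape[1]} shorter than widest kernel "
            f"{max(arch.conv_kernels)}"
        )
    X = U
    layers = []
    for i, k in enumerate(arch.conv_kernels, 1):
        W = params.arrays[f"{prefix}_conv{i}_W"]
        b = params.arrays[f"{prefix}_conv{i}_b"]
        Xcol = _im2col(X, k)
        Y = Xcol @ W.reshape(W.shape[0], -1).T + b
        A = np.maximum(Y, 0.0)
        layers.append({"Xcol": Xcol, "relu_mask": Y > 0, "W": W, "i": i, "in_shape": X.shape})
        X = A
    return X, {"layers": layers, "prefix": prefix}


def _conv_stack_backward(dH: np.ndarray, cache: dict, grads: dict) -> np.ndarray:
    prefix = cache["prefix"]
    dX = dH
    for layer in reversed(cache["layers"]):
        W, i = layer["W"], layer["i"]
        c_out, k, c_in = W.shape
        dY = dX * layer["relu_mask"]
        grads[f"{prefix}_conv{i}_W"] += np.tensordot(
            dY, layer["Xcol"], axes=([0, 1], [0, 1])
        ).reshape(W.shape)
        grads[f"{prefix}_conv{i}_b"] += dY.sum(axis=(0, 1))
        dXcol = (dY @ W.reshape(c_out, -1)).reshape(*dY.shape[:2], k, c_in)
        B, L, _ = layer["in_shape"]
        pad = k // 2
        dXp = np.zeros((B, L + 2 * pad, c_in))
        for j in range(k):
            dXp[:, j : j + L] += dXcol[:, :, j]
        dX = dXp[:, pad : pad + L]
    return dX


def _masked_max_pool_forward(
    H: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, dict]:
    if not np.all(mask.sum(axis=1) >= 1):
        raise InvalidInputError("every sample needs at least one unmasked position")
    neg = np.where(mask[..., None] == 1, H, -np.inf)
    idx = neg.argmax(axis=1)  # (B, C)
    pooled = np.take_along_axis(H, idx[:, None, :], axis=1)[:, 0, :]
    return pooled, {"idx": idx, "shape": H.shape}


def _masked_max_pool_backward(dp: np.ndarray, cache: dict) -> np.ndarray:
    dH = np.zeros(cache["shape"])
    np.put_along_axis(dH, cache["idx"][:, None, :], dp[:, None, :], axis=1)
    return dH


def _attention_forward(
    U: np.ndarray, params: ModelParams, prefix: str, mask: np.ndarray
) -> tuple[np.ndarray, dict]:
    a = params.arrays
    Wq, Wk, Wv = a[f"{prefix}_Wq"], a[f"{prefix}_Wk"], a[f"{prefix}_Wv"]
    scale = np.sqrt(Wq.shape[0])
    q = U @ Wq.T
    k = U @ Wk.T
    v = U @ Wv.T
    # in-place masked softmax over keys; large finite penalty instead of -inf
    # so fully padded key columns underflow to exactly zero weight
    logits = q @ k.transpose(0, 2, 1)  # (B, L, L)
    logits *= 1.0 / scale
    logits += ((mask == 0) * np.asarray(-1e30, dtype=logits.dtype))[:, None, :]
    logits -= logits.max(axis=2, keepdims=True)
    np.exp(logits, out=logits)
    logits /= logits.sum(axis=2, keepdims=True)
    A = logits
    G = (A @ v) * mask[..., None].astype(v.dtype)  # zero rows at masked queries
    return G, {
        "U": U, "q": q, "k": k, "v": v, "A": A,
        "mask": mask, "scale": scale, "prefix": prefix,
    }


def _attention_backward(dG: np.ndarray, cache: dict, grads: dict) -> np.ndarray:
    p, scale, mask = cache["prefix"], cache["scale"], cache["mask"]
    U, q, k, v, A = cache["U"], cache["q"], cache["k"], cache["v"], cache["A"]
    a = grads
    dG = dG * mask[..., None].astype(dG.dtype)
    dv = A.transpose(0, 2, 1) @ dG
    dA = dG @ v.transpose(0, 2, 1)
    dA -= (dA * A).sum(axis=2, keepdims=True)
    dA *= A
    dlogits = dA
    dq = dlogits @ k / scale
    dk = dlogits.transpose(0, 2, 1) @ q / scale
    for name, dz in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
        a[f"{p}_{name}"] += np.tensordot(dz, U, axes=([0, 1], [0, 1]))
    arrays = cache["params_arrays"]
    dU = (
        dq @ arrays[f"{p}_Wq"]
        + dk @ arrays[f"{p}_Wk"]
        + dv @ arrays[f"{p}_Wv"]
    )
    return dU


def _masked_mean_forward(G: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, dict]:
    counts = mask.sum(axis=1)
    if np.any(counts < 1):
        raise InvalidInputError("every sample needs at least one unmasked position")
    pooled = (G * mask[..., None].astype(G.dtype)).sum(axis=1) / counts[:, None].astype(G.dtype)
    return pooled, {"mask": mask, "counts": counts, "L": G.shape[1]}


def _masked_mean_backward(dp: np.ndarray, cache: dict) -> np.ndarray:
    mask, counts = cache["mask"], cache["counts"]
    m = mask[..., None].astype(dp.dtype)
    return m * dp[:, None, :] / counts[:, None, None].astype(dp.dtype)


def _fc_head_forward(
    z: np.ndarray,
    params: ModelParams,
    mode: Mode,
    dropout_rng: np.random.Generator | None,
) -> tuple[np.ndarray, dict]:
    a = params.arrays
    rate = params.arch.dropout
    cache: dict = {"z": z, "mode": mode}
    h = z
    for i in (1, 2):
        y = h @ a[f"fc{i}_W"].T + a[f"fc{i}_b"]
        act = np.maximum(y, 0.0)
        drop = None
        if mode == "train" and rate > 0.0:
            if dropout_rng is None:
                raise ConfigurationError("training mode requires a dropout RNG")
            drop = ((dropout_rng.random(act.shape) >= rate) / (1.0 - rate)).astype(
                act.dtype, copy=False
            )
            act = act * drop
        cache[f"h{i}_in"] = h
        cache[f"relu{i}"] = y > 0
        cache[f"drop{i}"] = drop
        h = act
    logit = (h @ a["fc3_W"].T + a["fc3_b"])[:, 0]
    cache["h3_in"] = h
    return logit, cache


def _fc_head_backward(dlogit: np.ndarray, cache: dict, params: ModelParams, grads: dict) -> np.ndarray:
    a = params.arrays
    dlogit2 = dlogit[:, None]
    grads["fc3_W"] += dlogit2.T @ cache["h3_in"]
    grads["fc3_b"] += dlogit2.sum(axis=0)
    dh = dlogit2 @ a["fc3_W"]
    for i in (2, 1):
        if cache[f"drop{i}"] is not None:
            dh = dh * cache[f"drop{i}"]
        dy = dh * cache[f"relu{i}"]
        grads[f"fc{i}_W"] += dy.T @ cache[f"h{i}_in"]
        grads[f"fc{i}_b"] += dy.sum(axis=0)
        dh = dy @ a[f"fc{i}_W"]
    return dh  # = dz


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Full batched forward/backward


def forward_batch(
    pep: ProfileBatch,
    pro: ProfileBatch,
    params: ModelParams,
    mode: Mode = "eval",
    dropout_rng: np.random.Generator | None = None,
) -> tuple[dict, dict]:
    """Run the whole network on a batch; returns (outputs, caches).

    ``outputs`` has ``pair_probs`` (B,), ``pair_logits`` (B,),
    ``residue_probs`` (B, L_pep) and ``residue_logits``.
    """
    caches: dict = {}
    U_pep, caches["emb_pep"] = _embed_forward(pep, params)
    U_pro, caches["emb_pro"] = _embed_forward(pro, params)
    H_pep, caches["conv_pep"] = _conv_stack_forward(U_pep, params, "pep")
    H_pro, caches["conv_pro"] = _conv_stack_forward(U_pro, params, "pro")
    pep_cnn, caches["pool_pep"] = _masked_max_pool_forward(H_pep, pep.mask)
    pro_cnn, caches["pool_pro"] = _masked_max_pool_forward(H_pro, pro.mask)
    G_pep, caches["att_pep"] = _attention_forward(U_pep, params, "pep", pep.mask)
    G_pro, caches["att_pro"] = _attention_forward(U_pro, params, "pro", pro.mask)
    caches["att_pep"]["params_arrays"] = params.arrays
    caches["att_pro"]["params_arrays"] = params.arrays
    pep_att, caches["mean_pep"] = _masked_mean_forward(G_pep, pep.mask)
    pro_att, caches["mean_pro"] = _masked_mean_forward(G_pro, pro.mask)
    z = np.concatenate([pep_cnn, pro_cnn, pep_att, pro_att], axis=1)
    pair_logit, caches["fc"] = _fc_head_forward(z, params, mode, dropout_rng)
    res_logit = H_pep @ params.arrays["res_W"] + params.arrays["res_c"]
    caches["H_pep"] = H_pep
    caches["dims"] = (pep_cnn.shape[1], pro_cnn.shape[1], pep_att.shape[1])
    outputs = {
        "pair_logits": pair_logit,
        "pair_probs": _sigmoid(pair_logit),
        "residue_logits": res_logit,
        "residue_probs": _sigmoid(res_logit),
    }
    return outputs, caches


def zero_grads(params: ModelParams) -> dict[str, np.ndarray]:
    return {k: np.zeros_like(v) for k, v in params.arrays.items()}


def backward_batch(
    dlogit_pair: np.ndarray,
    dlogit_res: np.ndarray,
    caches: dict,
    params: ModelParams,
    grads: dict[str, np.ndarray],
) -> None:
    """Accumulate gradients of a scalar loss into ``grads``.

    ``dlogit_pair`` (B,) and ``dlogit_res`` (B, L_pep) are the loss gradients
    with respect to the pre-sigmoid logits of the two heads.
    """
    H_pep = caches["H_pep"]
    grads["res_W"] += np.tensordot(dlogit_res, H_pep, axes=([0, 1], [0, 1]))
    grads["res_c"] += dlogit_res.sum()
    dH_pep_res = dlogit_res[..., None] * params.arrays["res_W"]

    dz = _fc_head_backward(dlogit_pair, caches["fc"], params, grads)
    c_pep, c_pro, d_k = caches["dims"]
    d_pep_cnn = dz[:, :c_pep]
    d_pro_cnn = dz[:, c_pep : c_pep + c_pro]
    d_pep_att = dz[:, c_pep + c_pro : c_pep + c_pro + d_k]
    d_pro_att = dz[:, c_pep + c_pro + d_k :]

    dG_pep = _masked_mean_backward(d_pep_att, caches["mean_pep"])
    dG_pro = _masked_mean_backward(d_pro_att, caches["mean_pro"])
    dU_pep_att = _attention_backward(dG_pep, caches["att_pep"], grads)
    dU_pro_att = _attention_backward(dG_pro, caches["att_pro"], grads)

    dH_pep = _masked_max_pool_backward(d_pep_cnn, caches["pool_pep"]) + dH_pep_res
    dH_pro = _masked_max_pool_backward(d_pro_cnn, caches["pool_pro"])
    dU_pep = _conv_stack_backward(dH_pep, caches["conv_pep"], grads) + dU_pep_att
    dU_pro = _conv_stack_backward(dH_pro, caches["conv_pro"], grads) + dU_pro_att

    _embed_backward(dU_pep, caches["emb_pep"], grads)
    _embed_backward(dU_pro, caches["emb_pro"], grads)


# ---------------------------------------------------------------------------
# Single-sample operation surface


def channel_embed(profile: FeatureProfile, params: ModelParams, role: Role) -> np.ndarray:
    """Embed one profile: per-row concat of 3 categorical lookups + numeric affine map."""
    if profile.role != role:
        raise InvalidInputError(f"profile role {profile.role} != requested {role}")
    batch = ProfileBatch.from_profiles([profile])
    U, _ = _embed_forward(batch, params)
    return U[0]


def conv_features(U: np.ndarray, params: ModelParams, role: Role) -> np.ndarray:
    """Per-position CNN features H (pre-pooling), 'same' padding, final ReLU."""
    prefix = "pep" if role == "peptide" else "pro"
    H, _ = _conv_stack_forward(U[None], params, prefix)
    return H[0]


def masked_max_pool(H: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Column-wise max over unmasked positions only."""
    pooled, _ = _masked_max_pool_forward(H[None], np.asarray(mask)[None])
    return pooled[0]


def attend(U: np.ndarray, w: AttentionWeights, mask: np.ndarray | None = None) -> np.ndarray:
    """Single-head scaled dot-product self-attention over unmasked positions.

    g_i = sum_j softmax_j(q_i . k_j / sqrt(d_k)) v_j with the softmax taken
    over unmasked keys only.
    """
    N = U.shape[0]
    mask = np.ones(N, dtype=np.int64) if mask is None else np.asarray(mask)
    if mask.sum() < 1:
        raise InvalidInputError("all positions are masked")
    q = U @ w.W_q.T
    k = U @ w.W_k.T
    v = U @ w.W_v.T
    logits = q @ k.T / w.scale
    logits = np.where(mask[None, :] == 1, logits, -np.inf)
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    A = e / e.sum(axis=1, keepdims=True)
    return A @ v


def attention_pool(G: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Masked mean of attention outputs over unmasked positions."""
    pooled, _ = _masked_mean_forward(G[None], np.asarray(mask)[None])
    return pooled[0]


def binary_head(
    pep_cnn: np.ndarray,
    pro_cnn: np.ndarray,
    pep_att: np.ndarray,
    pro_att: np.ndarray,
    params: ModelParams,
    dropout_active: bool = False,
    dropout_rng: np.random.Generator | None = None,
) -> float:
    """Three FC layers (dropout after the first two in training) + sigmoid."""
    z = np.concatenate([pep_cnn, pro_cnn, pep_att, pro_att])[None]
    expected = params.arrays["fc1_W"].shape[1]
    if z.shape[1] != expected:
        raise ConfigurationError(f"binary head expects {expected} inputs, got {z.shape[1]}")
    mode: Mode = "train" if dropout_active else "eval"
    logit, _ = _fc_head_forward(z, params, mode, dropout_rng)
    return float(_sigmoid(logit)[0])


def residue_scores(H_pep: np.ndarray, w: ResidueHeadWeights) -> np.ndarray:
    """Per-position binding probability b_j = sigma(W_pep . h_j + c)."""
    return _sigmoid(H_pep @ w.W_pep + w.c)


def forward(
    sample: PairSample,
    params: ModelParams,
    mode: Mode = "eval",
    dropout_rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray]:
    """Full forward pass for one pair: (interaction probability, residue probabilities)."""
    pep = ProfileBatch.from_profiles([sample.peptide])
    pro = ProfileBatch.from_profiles([sample.protein])
    out, _ = forward_batch(pep, pro, params, mode, dropout_rng)
    return float(out["pair_probs"][0]), out["residue_probs"][0]
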