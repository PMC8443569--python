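"""Benchmark construction: negative sampling and homology-aware CV splitting.

Interaction tables pair peptide and protein identifiers with binary labels
and optional per-residue binding vectors. Negatives are drawn uniformly from
the non-interacting peptide x protein combinations at a fixed ratio per
positive. Cross-validation folds come in four regimes: ``random`` (plain
k-fold over pairs) and three homology-aware settings where single-linkage
clusters of similar sequences (normalized Smith-Waterman >= t) never
straddle the train/test boundary: ``novel_protein``, ``novel_peptide`` and
``novel_pair`` (a k x k cluster-grid design; k=3 gives the usual 9 folds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .exceptions import ConfigurationError, InvalidInputError
from .featurization import SequenceRecord

Setting = Literal["random", "novel_protein", "novel_peptide", "novel_pair"]


@dataclass
class PairRecord:
    """One (peptide, protein) pair with its label and optional binding vector."""

    peptide_id: str
    protein_id: str
    label: int
    binding_vector: np.ndarray | None = None

    def key(self) -> tuple[str, str]:
        return (self.peptide_id, self.protein_id)


@dataclass
class InteractionTable:
    """Pairs plus id -> sequence maps (sequences may be absent for id-only work)."""

    pairs: list[PairRecord]
    peptides: dict[str, SequenceRecord | None] = field(default_factory=dict)
    proteins: dict[str, SequenceRecord | None] = field(default_factory=dict)

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.pairs:
            if rec.key() in seen:
                raise InvalidInputError(f"duplicate pair {rec.key()}")
            seen.add(rec.key())
            if self.peptides and rec.peptide_id not in self.peptides:
                raise InvalidInputError(f"unresolvable peptide id {rec.peptide_id}")
            if self.proteins and rec.protein_id not in self.proteins:
                raise InvalidInputError(f"unresolvable protein id {rec.protein_id}")
            if rec.binding_vector is not None:
                pep = self.peptides.get(rec.peptide_id)
                if pep is not None and len(rec.binding_vector) != len(pep):
                    raise InvalidInputError(
                        f"binding vector length {len(rec.binding_vector)} != "
                        f"peptide length {len(pep)} for pair {rec.key()}"
                    )

    @property
    def n_positive(self) -> int:
        return sum(1 for r in self.pairs if r.label == 1)

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# Sequence similarity and clustering

#: Standard protein local-alignment scoring: BLOSUM62, gap open 11, extend 1.
def _aligner(matrix: str = "BLOSUM62", gap_open: float = 11.0, gap_extend: float = 1.0):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def normalized_sw(a: str, b: str, aligner=None) -> float:
    """Self-normalized Smith-Waterman similarity in [0, 1].

    SW(a,b) / sqrt(SW(a,a) * SW(b,b)); symmetric, 1.0 for identical sequences.
    """
    if not a or not b:
        raise InvalidInputError("empty sequence")
    aligner = aligner or _aligner()
    saa = aligner.score(a, a)
    sbb = aligner.score(b, b)
    if saa <= 0 or sbb <= 0:
        return 0.0
    sab = aligner.score(a, b)
    if sab <= 0:
        return 0.0
    return float(min(1.0, sab / np.sqrt(saa * sbb)))


def similarity_matrix(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Dense pairwise normalized SW matrix over a small id -> sequence map."""
    ids = sorted(seqs)
    aligner = _aligner()
    self_scores = {i: aligner.score(seqs[i], seqs[i]) for i in ids}
    n = len(ids)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            saa, sbb = self_scores[ids[i]], self_scores[ids[j]]
            if saa <= 0 or sbb <= 0:
                s = 0.0
            else:
                s = max(0.0, aligner.score(seqs[ids[i]], seqs[ids[j]])) / np.sqrt(saa * sbb)
            sim[i, j] = sim[j, i] = min(1.0, float(s))
    return ids, sim


def cluster_entities(seqs: dict[str, str], t: float) -> dict[str, str]:
    """Single-linkage clusters: connected components of the >= t similarity graph.

    Cluster ids are the lexicographically smallest member id of each component.
    """
    if not 0.0 < t <= 1.0:
        raise InvalidInputError(f"threshold must be in (0, 1], got {t}")
    ids, sim = similarity_matrix(seqs)
    parent = list(range(len(ids)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if sim[i, j] >= t:
                parent[find(i)] = find(j)
    members: dict[int, list[str]] = {}
    for i, name in enumerate(ids):
        members.setdefault(find(i), []).append(name)
    out: dict[str, str] = {}
    for group in members.values():
        label = min(group)
        for name in group:
            out[name] = label
    return out


# ---------------------------------------------------------------------------
# Folds


@dataclass
class FoldPlan:
    """Train/test pair-index partitions under a named splitting regime."""

    setting: Setting
    threshold: float | None
    folds: list[tuple[np.ndarray, np.ndarray]]
    pep_clusters: dict[str, str] = field(default_factory=dict)
    pro_clusters: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "setting": self.setting,
                "threshold": self.threshold,
                "seed": self.seed,
                "folds": [
                    {"train": np.asarray(tr).tolist(), "test": np.asarray(te).tolist()}
                    for tr, te in self.folds
                ],
                "pep_clusters": self.pep_clusters,
                "pro_clusters": self.pro_clusters,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "FoldPlan":
        d = json.loads(text)
        return cls(
            setting=d["setting"],
            threshold=d["threshold"],
            folds=[
                (np.asarray(f["train"], dtype=np.int64), np.asarray(f["test"], dtype=np.int64))
                for f in d["folds"]
            ],
            pep_clusters=d.get("pep_clusters", {}),
            pro_clusters=d.get("pro_clusters", {}),
            seed=d.get("seed", 0),
        )


def _cluster_groups(
    clusters: dict[str, str], weights: dict[str, int], k: int, rng: np.random.Generator
) -> list[set[str]]:
    """Greedily balance cluster ids into k groups by total pair weight."""
    cluster_ids = sorted(set(clusters.values()))
    if len(cluster_ids) < k:
        raise ConfigurationError(
            f"need at least {k} clusters, have {len(cluster_ids)}"
        )
    cw = {c: 0 for c in cluster_ids}
    for ent, c in clusters.items():
        cw[c] += weights.get(ent, 0)
    order = sorted(cluster_ids, key=lambda c: (-cw[c], c))
    rng.shuffle(cluster_ids)  # seeded tie-break via secondary shuffle order
    rank = {c: i for i, c in enumerate(cluster_ids)}
    order = sorted(order, key=lambda c: (-cw[c], rank[c]))
    groups: list[set[str]] = [set() for _ in range(k)]
    totals = [0] * k
    for c in order:
        g = int(np.argmin(totals))
        groups[g].add(c)
        totals[g] += cw[c]
    return groups


def make_folds(
    table: InteractionTable,
    setting: Setting,
    t: float | None = None,
    k: int = 5,
    seed: int = 0,
) -> FoldPlan:
    """Build a seeded FoldPlan under the requested splitting regime.

    ``random``: k-fold over pairs. ``novel_protein`` / ``novel_peptide``:
    clusters of that entity are assigned to k groups and pairs follow their
    entity's cluster. ``novel_pair``: peptide and protein cluster groups form
    a k x k grid; fold (i, j) tests on pairs whose peptide cluster is in
    group i AND protein cluster in group j, training on pairs sharing
    neither; some pairs go unused per fold by construction.
    """
    if k < 2:
        raise ConfigurationError("k must be at least 2")
    rng = np.random.default_rng(seed)
    n = len(table)
    idx = np.arange(n)

    if setting == "random":
        perm = rng.permutation(n)
        parts = np.array_split(perm, k)
        folds = [
            (np.sort(np.concatenate(parts[:i] + parts[i + 1 :])), np.sort(parts[i]))
            for i in range(k)
        ]
        return FoldPlan(setting, None, folds, seed=seed)

    if t is None:
        raise ConfigurationError(f"setting {setting} requires a similarity threshold")

    def seqs_of(records: dict[str, SequenceRecord | None]) -> dict[str, str]:
        out = {}
        for name, rec in records.items():
            if rec is None:
                raise InvalidInputError(f"sequence required for clustering: {name}")
            out[name] = rec.sequence
        return out

    pep_clusters = cluster_entities(seqs_of(table.peptides), t) if setting != "novel_protein" else {}
    pro_clusters = cluster_entities(seqs_of(table.proteins), t) if setting != "novel_peptide" else {}

    pep_of = np.array([r.peptide_id for r in table.pairs])
    pro_of = np.array([r.protein_id for r in table.pairs])

    def entity_weights(ids: np.ndarray) -> dict[str, int]:
        w: dict[str, int] = {}
        for e in ids:
            w[e] = w.get(e, 0) + 1
        return w

    if setting in ("novel_protein", "novel_peptide"):
        clusters = pro_clusters if setting == "novel_protein" else pep_clusters
        ids = pro_of if setting == "novel_protein" else pep_of
        groups = _cluster_groups(clusters, entity_weights(ids), k, rng)
        pair_cluster = np.array([clusters[e] for e in ids])
        folds = []
        for g in groups:
            test_mask = np.isin(pair_cluster, sorted(g))
            folds.append((idx[~test_mask], idx[test_mask]))
        return FoldPlan(setting, t, folds, pep_clusters, pro_clusters, seed)

    if setting == "novel_pair":
        kk = 3 if k == 5 else k  # grid dimension; default grid is 3 x 3
        pep_groups = _cluster_groups(pep_clusters, entity_weights(pep_of), kk, rng)
        pro_groups = _cluster_groups(pro_clusters, entity_weights(pro_of), kk, rng)
        pair_pc = np.array([pep_clusters[e] for e in pep_of])
        pair_qc = np.array([pro_clusters[e] for e in pro_of])
        folds = []
        for gp in pep_groups:
            in_p = np.isin(pair_pc, sorted(gp))
            for gq in pro_groups:
                in_q = np.isin(pair_qc, sorted(gq))
                test_mask = in_p & in_q
                train_mask = ~in_p & ~in_q
                folds.append((idx[train_mask], idx[test_mask]))
        return FoldPlan(setting, t, folds, pep_clusters, pro_clusters, seed)

    raise ConfigurationError(f"unknown setting {setting!r}")


def leakage_check(
    plan: FoldPlan, table: InteractionTable
) -> tuple[bool, list[tuple[int, str]]]:
    """Verify each fold's cluster-disjointness contract; list violating entities."""
    violations: list[tuple[int, str]] = []
    pep_of = [r.peptide_id for r in table.pairs]
    pro_of = [r.protein_id for r in table.pairs]

    def clusters_in(ids: list[str], idxs: np.ndarray, cmap: dict[str, str]) -> set[str]:
        return {cmap[ids[i]] for i in idxs}

    for f, (train, test) in enumerate(plan.folds):
        if plan.setting in ("novel_protein", "novel_pair"):
            shared = clusters_in(pro_of, train, plan.pro_clusters) & clusters_in(
                pro_of, test, plan.pro_clusters
            )
            for i in test:
                if plan.pro_clusters[pro_of[i]] in shared:
                    violations.append((f, pro_of[i]))
        if plan.setting in ("novel_peptide", "novel_pair"):
            shared = clusters_in(pep_of, train, plan.pep_clusters) & clusters_in(
                pep_of, test, plan.pep_clusters
            )
            for i in test:
                if plan.pep_clusters[pep_of[i]] in shared:
                    violations.append((f, pep_of[i]))
    return (len(violations) == 0, violations)


def exhaustive_pairs(
    peptide_ids: list[str], protein_ids: list[str], label: int = 0
) -> InteractionTable:
    """All peptide x protein combinations as one table (screening candidates)."""
    pairs = [
        PairRecord(p, q, label)
        for p in sorted(set(peptide_ids))
        for q in sorted(set(protein_ids))
    ]
    return InteractionTable(pairs)


# ---------------------------------------------------------------------------
# Negative sampling


def sample_negatives(table: InteractionTable, ratio: int, seed: int = 0) -> InteractionTable:
    """Add ``ratio`` shuffled negatives per positive, uniformly without replacement.

    Negatives are drawn from peptide x protein combinations excluding known
    positives and each other; the output table has (1 + ratio) x n_positive rows.
    """
    if ratio == 0:
        return table
    if ratio < 0:
        raise InvalidInputError("ratio must be non-negative")
    positives = [r for r in table.pairs if r.label == 1]
    pep_ids = sorted(table.peptides) if table.peptides else sorted({r.peptide_id for r in table.pairs})
    pro_ids = sorted(table.proteins) if table.proteins else sorted({r.protein_id for r in table.pairs})
    n_pep, n_pro = len(pep_ids), len(pro_ids)
    need = ratio * len(positives)
    total = n_pep * n_pro
    pep_index = {p: i for i, p in enumerate(pep_ids)}
    pro_index = {p: i for i, p in enumerate(pro_ids)}
    # exclude every existing pair (positives and any pre-existing negatives)
    forbidden = {pep_index[r.peptide_id] * n_pro + pro_index[r.protein_id] for r in table.pairs}
    if total - len(forbidden) < need:
        raise InvalidInputError(
            f"only {total - len(forbidden)} non-positive combinations for {need} negatives"
        )
    rng = np.random.default_rng(seed)
    chosen: set[int] = set()
    # rejection sampling stays efficient while the draw is a small fraction of
    # the space; fall back to exhaustive enumeration when it is not
    if need <= 0.5 * (total - len(forbidden)) and total > 4 * need:
        while len(chosen) < need:
            batch = rng.integers(0, total, size=2 * (need - len(chosen)))
            for code in batch:
                code = int(code)
                if code not in forbidden and code not in chosen:
                    chosen.add(code)
                    if len(chosen) == need:
                        break
    else:
        candidates = np.array(sorted(set(range(total)) - forbidden), dtype=np.int64)
        chosen = set(int(c) for c in rng.choice(candidates, size=need, replace=False))
    negatives = [
        PairRecord(pep_ids[code // n_pro], pro_ids[code % n_pro], 0)
        for code in sorted(chosen)
    ]
    out = InteractionTable(
        pairs=list(table.pairs) + negatives,
        peptides=dict(table.peptides),
        proteins=dict(table.proteins),
    )
    out.validate()
    return out
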