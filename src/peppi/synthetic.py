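"""Desk-scale synthetic peptide-protein interaction datasets.

The generator plants complementary k-mer motif pairs. Every peptide in the
pool carries one peptide motif from the library (at a recorded position)
and every protein carries one protein motif; a pair is positive exactly
when the two motifs are complementary partners, so the label is a property
of the *combination* and entity identity alone carries no signal — a model
can only generalize by learning the motif match. Binding vectors are 1 at
the planted peptide positions, optionally flipped with a label-noise rate.
Negative pairs are verified by exhaustive k-mer scan to contain no
complementary motif pair. Background residues are i.i.d. uniform over the
20 canonical letters, and sequences can be expanded from family ancestors
by point mutation so homology clustering has real structure to find.
Complementarity is symbolic — paired k-mers from a lookup — because the
generator exists to test learnability, not chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curation import InteractionTable, PairRecord
from .exceptions import ConfigurationError
from .featurization import CANONICAL_AA, SequenceRecord

#: Default library: one complementary 4-mer pair. With a single entry the
#: interaction rule is a pure conjunction — peptide carries the peptide
#: k-mer and protein carries the partner k-mer — which a small network
#: learns reliably; multi-entry libraries (labels require matching *which*
#: motif is present) are supported for harder benchmarks.
_DEFAULT_MOTIFS = [
    ("WYRK", "DEDL"),
]

#: Extended library for harder, match-based benchmarks.
MOTIF_LIBRARY_3 = [
    ("WYRK", "DEDL"),
    ("FHNM", "QSTV"),
    ("CPGI", "KRHA"),
]


@dataclass
class SyntheticConfig:
    """Generator settings; defaults give a small but learnable benchmark."""

    n_positives: int = 200
    negative_ratio: int = 5
    peptide_len_range: tuple[int, int] = (5, 50)
    protein_len_range: tuple[int, int] = (51, 300)
    motifs: list[tuple[str, str]] = field(default_factory=lambda: list(_DEFAULT_MOTIFS))
    planted_fraction: float = 0.7  # probability a pool sequence carries a motif
    label_noise: float = 0.0
    n_families: int = 0  # 0 = every sequence drawn independently
    copies_per_family: int = 4
    family_mutation_rate: float = 0.05
    pool_size: int | None = None  # sequences per side; None = sized automatically
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_noise < 0.5:
            raise ConfigurationError("label-noise rate must be in [0, 0.5)")
        lo, hi = self.peptide_len_range
        if not 1 <= lo <= hi <= 50:
            raise ConfigurationError("peptide lengths must stay within 1..50")
        plo, phi = self.protein_len_range
        if not 51 <= plo <= phi:
            raise ConfigurationError("protein lengths must exceed 50")
        if any(len(pm) > lo for pm, _ in self.motifs):
            raise ConfigurationError("motif longer than the minimum peptide length")
        if not 0.0 < self.planted_fraction <= 1.0:
            raise ConfigurationError("planted fraction must be in (0, 1]")


@dataclass
class GroundTruth:
    """What the generator planted, for oracle-style checks downstream."""

    motif_of_pair: dict[tuple[str, str], tuple[str, str]]
    motif_position: dict[tuple[str, str], int]  # peptide motif start (0-based)
    families: dict[str, str]  # sequence id -> family label


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(CANONICAL_AA), size=length))


def _contains_any_pair(pep: str, pro: str, motifs: list[tuple[str, str]]) -> bool:
    return any(pm in pep and qm in pro for pm, qm in motifs)


def _scrub(seq: str, kmers: list[str], rng: np.random.Generator) -> str:
    """Resample single positions until no listed k-mer survives."""
    s = list(seq)
    changed = True
    while changed:
        changed = False
        text = "".join(s)
        for km in kmers:
            pos = text.find(km)
            if pos >= 0:
                s[pos + int(rng.integers(len(km)))] = rng.choice(list(CANONICAL_AA))
                changed = True
                break
    return "".join(s)


def family_expand(
    ancestors: dict[str, str],
    copies: int,
    mutation_rate: float,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str]]:
    """Mutate each ancestor into ``copies`` descendants by i.i.d. substitutions.

    Returns (id -> sequence, id -> family label). Copy 0 is the unmutated
    ancestor itself.
    """
    if not 0.0 <= mutation_rate < 0.5:
        raise ConfigurationError("mutation rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    letters = list(CANONICAL_AA)
    seqs: dict[str, str] = {}
    families: dict[str, str] = {}
    for name in sorted(ancestors):
        seq = ancestors[name]
        for c in range(copies):
            cid = f"{name}_c{c}"
            if c == 0 or mutation_rate == 0.0:
                mutated = seq
            else:
                chars = list(seq)
                hits = rng.random(len(chars)) < mutation_rate
                for i in np.flatnonzero(hits):
                    choices = [x for x in letters if x != chars[i]]
                    chars[i] = choices[int(rng.integers(len(choices)))]
                mutated = "".join(chars)
            seqs[cid] = mutated
            families[cid] = name
    return seqs, families


def generate_dataset(
    cfg: SyntheticConfig,
) -> tuple[InteractionTable, GroundTruth]:
    """Generate a motif-driven interaction table with residue labels.

    Every pool sequence carries exactly one planted motif; a pair is
    positive iff its peptide and protein motifs are complementary partners.
    Binding vectors are 1 at the planted peptide positions, flipped with
    probability ``label_noise``. Negatives are verified to contain no
    complementary motif pair. Class ratio is 1:``negative_ratio``. Fully
    deterministic given the config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    motif_kmers_pep = [pm for pm, _ in cfg.motifs]
    motif_kmers_pro = [qm for _, qm in cfg.motifs]

    # pools sized so entities recur across pairs with both labels (identity
    # alone cannot separate the classes) while leaving comfortable headroom
    # for the required complementary positives and motif-free negatives
    M = len(cfg.motifs)
    p_match = cfg.planted_fraction**2 / M
    if cfg.pool_size is not None:
        n_pool = cfg.pool_size
    else:
        n_pool = max(
            2 * M,
            cfg.n_positives // 2,
            int(np.ceil(np.sqrt(2.5 * cfg.n_positives / p_match))),
            int(np.ceil(np.sqrt(2.5 * max(cfg.negative_ratio, 1) * cfg.n_positives / (1.0 - 0.9 * p_match)))),
        )
    n_pep = n_pro = n_pool

    def _make_pool(n: int, lo: int, hi: int, prefix: str) -> tuple[dict[str, str], dict[str, str]]:
        if cfg.n_families > 0:
            # one ancestor per family, so families coincide with homology clusters
            ancestors = {
                f"{prefix}fam{f}": _random_seq(rng, int(rng.integers(lo, hi + 1)))
                for f in range(cfg.n_families)
            }
            return family_expand(
                ancestors, cfg.copies_per_family, cfg.family_mutation_rate,
                seed=int(rng.integers(2**31)),
            )
        seqs = {f"{prefix}{i:05d}": _random_seq(rng, int(rng.integers(lo, hi + 1))) for i in range(n)}
        return seqs, {k: k for k in seqs}

    pep_seqs, pep_fams = _make_pool(n_pep, *cfg.peptide_len_range, "pep_")
    pro_seqs, pro_fams = _make_pool(n_pro, *cfg.protein_len_range, "pro_")

    # scrub incidental motifs so plants are the only signal, then plant one
    # library motif into every sequence at a recorded position
    pep_seqs = {k: _scrub(v, motif_kmers_pep, rng) for k, v in pep_seqs.items()}
    pro_seqs = {k: _scrub(v, motif_kmers_pro, rng) for k, v in pro_seqs.items()}

    pep_motif: dict[str, int] = {}  # -1 = unplanted
    pep_pos: dict[str, int] = {}
    for pid in sorted(pep_seqs):
        if rng.random() >= cfg.planted_fraction:
            pep_motif[pid] = -1
            continue
        m = int(rng.integers(len(cfg.motifs)))
        pm = cfg.motifs[m][0]
        seq = pep_seqs[pid]
        pos = int(rng.integers(0, len(seq) - len(pm) + 1))
        pep_seqs[pid] = seq[:pos] + pm + seq[pos + len(pm):]
        pep_motif[pid], pep_pos[pid] = m, pos
    pro_motif: dict[str, int] = {}
    for qid in sorted(pro_seqs):
        if rng.random() >= cfg.planted_fraction:
            pro_motif[qid] = -1
            continue
        m = int(rng.integers(len(cfg.motifs)))
        qm = cfg.motifs[m][1]
        seq = pro_seqs[qid]
        qpos = int(rng.integers(0, len(seq) - len(qm) + 1))
        pro_seqs[qid] = seq[:qpos] + qm + seq[qpos + len(qm):]
        pro_motif[qid] = m

    pep_ids = sorted(pep_seqs)
    pro_ids = sorted(pro_seqs)
    truth = GroundTruth({}, {}, {**pep_fams, **pro_fams})
    pairs: list[PairRecord] = []
    used: set[tuple[str, str]] = set()

    matching = [
        (pid, qid)
        for pid in pep_ids
        for qid in pro_ids
        if pep_motif[pid] >= 0 and pep_motif[pid] == pro_motif[qid]
    ]
    if len(matching) < cfg.n_positives:
        raise ConfigurationError(
            f"only {len(matching)} complementary combinations for "
            f"{cfg.n_positives} positives; enlarge the pools"
        )
    for idx in rng.choice(len(matching), size=cfg.n_positives, replace=False):
        pid, qid = matching[int(idx)]
        used.add((pid, qid))
        m = pep_motif[pid]
        pm, qm = cfg.motifs[m]
        pos = pep_pos[pid]
        bv = np.zeros(len(pep_seqs[pid]), dtype=np.int64)
        bv[pos : pos + len(pm)] = 1
        if cfg.label_noise > 0:
            flips = rng.random(len(bv)) < cfg.label_noise
            bv = np.where(flips, 1 - bv, bv)
        pairs.append(PairRecord(pid, qid, 1, bv))
        truth.motif_of_pair[(pid, qid)] = (pm, qm)
        truth.motif_position[(pid, qid)] = pos

    # negatives: random unused pairings with no complementary motif pair
    need = cfg.negative_ratio * len(pairs)
    budget = 1000 * (need + 1)
    guard = 0
    while need > 0:
        guard += 1
        if guard > budget:
            raise ConfigurationError("cannot find enough motif-free negative pairs")
        pid = pep_ids[int(rng.integers(len(pep_ids)))]
        qid = pro_ids[int(rng.integers(len(pro_ids)))]
        if (pid, qid) in used:
            continue
        if _contains_any_pair(pep_seqs[pid], pro_seqs[qid], cfg.motifs):
            continue
        used.add((pid, qid))
        pairs.append(PairRecord(pid, qid, 0, None))
        need -= 1

    peptides = {k: SequenceRecord(k, "peptide", v) for k, v in pep_seqs.items()}
    proteins = {k: SequenceRecord(k, "protein", v) for k, v in pro_seqs.items()}
    table = InteractionTable(pairs, peptides, proteins)
    table.validate()
    return table, truth
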