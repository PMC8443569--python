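"""Sequence featurization: residue encodings and padded multi-channel profiles.

Every sequence (peptide or protein) is turned into a :class:`FeatureProfile`
holding three categorical code tracks (amino-acid type, secondary-structure
combination, polarity/hydropathy combination), a dense numeric matrix
(disorder scores, plus a normalized PSSM for proteins) and a padding mask.
Evolutionary, secondary-structure and disorder features come from pluggable
providers; a deterministic stub provider generates them from the sequence
alone so the whole pipeline runs without external tools.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .exceptions import ConfigurationError, InvalidInputError, ProviderError

logger = logging.getLogger(__name__)

MAX_PEPTIDE_LEN = 50
DEFAULT_PROTEIN_PAD = 800

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN_AA = "X"

SS_CLASSES = "HEC"  # helix, strand, coil

# Side-chain polarity and Kyte-Doolittle hydropathy groupings. Each residue is
# assigned a (polarity, hydropathy) class pair; the categorical code indexes the
# cross-product of observed pairs. 'X' gets its own "unknown" category.
POLARITY_CLASSES = ("nonpolar", "polar", "charged", "unknown")
HYDROPATHY_CLASSES = ("hydrophobic", "neutral", "hydrophilic", "unknown")

DEFAULT_POLHYD_TABLE: dict[str, tuple[str, str]] = {
    "A": ("nonpolar", "hydrophobic"),
    "C": ("nonpolar", "hydrophobic"),
    "D": ("charged", "hydrophilic"),
    "E": ("charged", "hydrophilic"),
    "F": ("nonpolar", "hydrophobic"),
    "G": ("nonpolar", "neutral"),
    "H": ("charged", "hydrophilic"),
    "I": ("nonpolar", "hydrophobic"),
    "K": ("charged", "hydrophilic"),
    "L": ("nonpolar", "hydrophobic"),
    "M": ("nonpolar", "hydrophobic"),
    "N": ("polar", "hydrophilic"),
    "P": ("nonpolar", "neutral"),
    "Q": ("polar", "hydrophilic"),
    "R": ("charged", "hydrophilic"),
    "S": ("polar", "neutral"),
    "T": ("polar", "neutral"),
    "V": ("nonpolar", "hydrophobic"),
    "W": ("nonpolar", "neutral"),
    "Y": ("polar", "neutral"),
    "X": ("unknown", "unknown"),
}


@dataclass(frozen=True)
class ResidueAlphabet:
    """The 21-letter residue alphabet: 20 canonical amino acids plus 'X'.

    Codes run 1..21; 0 is reserved for padding. Any letter outside the 20
    canonical ones maps to the code of 'X'.
    """

    symbols: tuple[str, ...] = tuple(CANONICAL_AA + UNKNOWN_AA)

    def __post_init__(self) -> None:
        if len(self.symbols) != 21 or len(set(self.symbols)) != 21:
            raise ConfigurationError("alphabet must have 21 distinct symbols")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def code_of(self, letter: str) -> int:
        """Integer code in 1..21 for a residue letter (unknowns map to 'X')."""
        letter = letter.upper()
        try:
            return self.symbols.index(letter) + 1
        except ValueError:
            return self.symbols.index(UNKNOWN_AA) + 1


DEFAULT_ALPHABET = ResidueAlphabet()

Role = Literal["peptide", "protein"]


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence with its role. Peptides are 1..50 residues, proteins >50."""

    id: str
    role: Role
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise InvalidInputError(f"{self.id}: empty sequence")
        if self.role == "peptide" and len(seq) > MAX_PEPTIDE_LEN:
            raise InvalidInputError(
                f"{self.id}: peptide length {len(seq)} exceeds {MAX_PEPTIDE_LEN}"
            )
        if self.role == "protein" and len(seq) <= MAX_PEPTIDE_LEN:
            raise InvalidInputError(
                f"{self.id}: protein length {len(seq)} must exceed {MAX_PEPTIDE_LEN}"
            )
        if self.role not in ("peptide", "protein"):
            raise InvalidInputError(f"{self.id}: unknown role {self.role!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FeatureProfile:
    """Padded multi-channel features for one sequence.

    ``numeric`` is L x 3 for peptides (disorder scores) and L x 23 for
    proteins (20 normalized PSSM columns then 3 disorder scores). Padded
    positions are zero in every channel and ``mask`` is 0 there.
    """

    aa_codes: np.ndarray
    ss_codes: np.ndarray
    polhyd_codes: np.ndarray
    numeric: np.ndarray
    mask: np.ndarray
    true_length: int
    role: Role

    def validate(self) -> None:
        L = len(self.mask)
        if not (
            len(self.aa_codes) == len(self.ss_codes) == len(self.polhyd_codes) == L
            and self.numeric.shape[0] == L
        ):
            raise InvalidInputError("profile channel lengths disagree")
        expect = np.zeros(L, dtype=np.int64)
        expect[: self.true_length] = 1
        if not np.array_equal(self.mask.astype(np.int64), expect):
            raise InvalidInputError("mask is not leading-ones")
        pad = self.mask == 0
        for arr in (self.aa_codes, self.ss_codes, self.polhyd_codes):
            if np.any(arr[pad] != 0):
                raise InvalidInputError("nonzero code at padded position")
        if np.any(self.numeric[pad] != 0.0):
            raise InvalidInputError("nonzero numeric feature at padded position")


def encode_residues(seq: str, alphabet: ResidueAlphabet = DEFAULT_ALPHABET) -> np.ndarray:
    """Encode a residue string as integer codes in 1..21.

    Non-standard letters collapse onto the 'X' code.
    """
    if not seq:
        raise InvalidInputError("empty sequence")
    lut = np.full(256, alphabet.code_of(UNKNOWN_AA), dtype=np.int64)
    for i, s in enumerate(alphabet.symbols):
        lut[ord(s)] = i + 1
        lut[ord(s.lower())] = i + 1
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def combine_ss_codes(
    seq: str, ss: str, alphabet: ResidueAlphabet = DEFAULT_ALPHABET
) -> np.ndarray:
    """Joint (amino acid, secondary structure) code: (aa-1)*3 + ss, in 1..63.

    The map is a bijection over the 21 x 3 cross-product of residue type and
    3-class secondary structure {H, E, C}.
    """
    if len(seq) != len(ss):
        raise InvalidInputError(
            f"sequence length {len(seq)} != secondary-structure length {len(ss)}"
        )
    bad = set(ss) - set(SS_CLASSES)
    if bad:
        raise InvalidInputError(f"unknown secondary-structure letters: {sorted(bad)}")
    aa = encode_residues(seq, alphabet)
    ss_code = np.array([SS_CLASSES.index(c) + 1 for c in ss], dtype=np.int64)
    return (aa - 1) * len(SS_CLASSES) + ss_code


def polhyd_code_table(
    table: dict[str, tuple[str, str]] | None = None,
    alphabet: ResidueAlphabet = DEFAULT_ALPHABET,
) -> dict[str, int]:
    """Letter -> categorical code over the polarity x hydropathy cross-product.

    Residues sharing both the polarity class and the hydropathy class share a
    code. Codes start at 1; 0 stays reserved for padding.
    """
    table = DEFAULT_POLHYD_TABLE if table is None else table
    missing = [s for s in alphabet.symbols if s not in table]
    if missing:
        raise ConfigurationError(f"polarity/hydropathy table missing letters: {missing}")
    for letter, (pol, hyd) in table.items():
        if pol not in POLARITY_CLASSES or hyd not in HYDROPATHY_CLASSES:
            raise ConfigurationError(f"unknown class pair for {letter}: {(pol, hyd)}")
    pair_codes: dict[tuple[str, str], int] = {}
    for pol in POLARITY_CLASSES:
        for hyd in HYDROPATHY_CLASSES:
            if any(table[s] == (pol, hyd) for s in alphabet.symbols):
                pair_codes[(pol, hyd)] = len(pair_codes) + 1
    return {s: pair_codes[table[s]] for s in alphabet.symbols}


def combine_polhyd_codes(
    seq: str,
    table: dict[str, tuple[str, str]] | None = None,
    alphabet: ResidueAlphabet = DEFAULT_ALPHABET,
) -> np.ndarray:
    """Per-residue polarity/hydropathy category codes for a sequence."""
    if not seq:
        raise InvalidInputError("empty sequence")
    codes = polhyd_code_table(table, alphabet)
    unknown = codes[UNKNOWN_AA]
    return np.array([codes.get(c.upper(), unknown) for c in seq], dtype=np.int64)


N_POLHYD_CODES = max(polhyd_code_table().values())
N_SS_CODES = 21 * len(SS_CLASSES)

# ---------------------------------------------------------------------------
# Feature providers


def _seq_seed(sequence: str, seed: int) -> int:
    digest = hashlib.sha256(f"{seed}:{sequence}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def stub_pssm(record: SequenceRecord, seed: int = 0) -> np.ndarray:
    """Deterministic stand-in PSSM: per-row normalized positive draws in [0,1].

    A pure function of (sequence, seed); rows resemble a per-position
    amino-acid probability profile, biased toward the observed residue.
    """
    rng = np.random.default_rng(_seq_seed("pssm:" + record.sequence, seed))
    n = len(record)
    raw = rng.gamma(shape=0.5, scale=1.0, size=(n, 20))
    aa = encode_residues(record.sequence)
    for i, code in enumerate(aa):
        if code <= 20:  # bias toward the observed canonical residue
            raw[i, code - 1] += 3.0
    return raw / raw.sum(axis=1, keepdims=True)


def stub_ss(record: SequenceRecord, seed: int = 0) -> str:
    """Deterministic 3-state secondary-structure string via a sticky Markov chain."""
    rng = np.random.default_rng(_seq_seed("ss:" + record.sequence, seed))
    stay = 0.85
    state = int(rng.integers(3))
    out = []
    for _ in range(len(record)):
        out.append(SS_CLASSES[state])
        if rng.random() > stay:
            state = int((state + 1 + rng.integers(2))) % 3
    return "".join(out)


def stub_disorder(record: SequenceRecord, seed: int = 0) -> np.ndarray:
    """Deterministic n x 3 disorder-score table, smoothed uniform noise in [0,1]."""
    rng = np.random.default_rng(_seq_seed("dis:" + record.sequence, seed))
    n = len(record)
    raw = rng.random((n + 4, 3))
    kernel = np.ones(5) / 5.0
    smoothed = np.stack([np.convolve(raw[:, j], kernel, mode="valid") for j in range(3)], axis=1)
    out = np.empty((n, 3))
    out[:] = smoothed[:n]
    return np.clip(out, 0.0, 1.0)


@dataclass
class FeatureProviders:
    """Pluggable per-sequence feature sources.

    Each provider maps a :class:`SequenceRecord` to its raw feature: an n x 20
    PSSM in [0,1], an n-letter secondary-structure string over {H,E,C}, or an
    n x 3 disorder-score matrix in [0,1]. The defaults are deterministic stubs
    seeded from a hash of the sequence, so no external tools are needed.
    """

    pssm_provider: Callable[[SequenceRecord], np.ndarray] = field(default=None)  # type: ignore[assignment]
    ss_provider: Callable[[SequenceRecord], str] = field(default=None)  # type: ignore[assignment]
    disorder_provider: Callable[[SequenceRecord], np.ndarray] = field(default=None)  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self) -> None:
        s = self.seed
        if self.pssm_provider is None:
            self.pssm_provider = lambda r: stub_pssm(r, s)
        if self.ss_provider is None:
            self.ss_provider = lambda r: stub_ss(r, s)
        if self.disorder_provider is None:
            self.disorder_provider = lambda r: stub_disorder(r, s)


def numeric_dim(role: Role) -> int:
    """Width of the dense numeric channel: 3 for peptides, 23 for proteins."""
    return 3 if role == "peptide" else 23


def build_profile(
    record: SequenceRecord,
    providers: FeatureProviders | None = None,
    pad_len: int | None = None,
    polhyd_table: dict[str, tuple[str, str]] | None = None,
) -> FeatureProfile:
    """Assemble the padded, masked multi-channel profile for one sequence.

    Peptides longer than ``pad_len`` are rejected; proteins longer than
    ``pad_len`` are tail-truncated (N-terminus kept) with a warning.
    """
    providers = providers or FeatureProviders()
    if pad_len is None:
        pad_len = MAX_PEPTIDE_LEN if record.role == "peptide" else DEFAULT_PROTEIN_PAD

    seq = record.sequence
    if len(seq) > pad_len:
        if record.role == "peptide":
            raise InvalidInputError(
                f"{record.id}: peptide length {len(seq)} exceeds pad length {pad_len}"
            )
        logger.warning(
            "%s: protein length %d exceeds pad length %d; tail-truncating",
            record.id, len(seq), pad_len,
        )
        warnings.warn(
            f"{record.id}: protein truncated from {len(seq)} to {pad_len} residues",
            stacklevel=2,
        )
        seq = seq[:pad_len]
        record = SequenceRecord(record.id, record.role, seq)

    n = len(seq)
    ss = providers.ss_provider(record)
    if len(ss) != n:
        raise ProviderError(f"{record.id}: SS provider returned length {len(ss)} != {n}")
    disorder = np.asarray(providers.disorder_provider(record), dtype=np.float64)
    if disorder.shape != (n, 3):
        raise ProviderError(f"{record.id}: disorder provider shape {disorder.shape} != {(n, 3)}")

    d_num = numeric_dim(record.role)
    numeric = np.zeros((pad_len, d_num))
    if record.role == "protein":
        pssm = np.asarray(providers.pssm_provider(record), dtype=np.float64)
        if pssm.shape != (n, 20):
            raise ProviderError(f"{record.id}: PSSM provider shape {pssm.shape} != {(n, 20)}")
        numeric[:n, :20] = pssm
        numeric[:n, 20:] = disorder
    else:
        numeric[:n] = disorder

    def _pad(codes: np.ndarray) -> np.ndarray:
        out = np.zeros(pad_len, dtype=np.int64)
        out[:n] = codes
        return out

    mask = np.zeros(pad_len, dtype=np.int64)
    mask[:n] = 1
    profile = FeatureProfile(
        aa_codes=_pad(encode_residues(seq)),
        ss_codes=_pad(combine_ss_codes(seq, ss)),
        polhyd_codes=_pad(combine_polhyd_codes(seq, polhyd_table)),
        numeric=numeric,
        mask=mask,
        true_length=n,
        role=record.role,
    )
    profile.validate()
    return profile
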