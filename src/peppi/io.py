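"""File formats: FASTA sequences, pair tables, feature sidecars, checkpoints.

Pair-table TSV dialect: columns ``peptide_id  protein_id  label  binding_vector``
where the binding vector is comma-separated 0/1 over the peptide's true
length, or ``-`` when absent. A feature manifest TSV maps sequence id to
sidecar paths: PSSM (whitespace n x 20 numeric text), secondary structure
(single-line string) and disorder (n x 3 TSV).
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .curation import InteractionTable, PairRecord
from .exceptions import InvalidInputError, ProviderError
from .featurization import FeatureProviders, SequenceRecord
from .network import ArchitectureConfig, ModelParams


def read_fasta(path: str | Path, role: str) -> dict[str, SequenceRecord]:
    """Load a multi-record FASTA as id -> SequenceRecord of one role."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise InvalidInputError(f"{path}: duplicate sequence id {rec.id}")
        records[rec.id] = SequenceRecord(rec.id, role, str(rec.seq))
    if not records:
        raise InvalidInputError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: dict[str, SequenceRecord], path: str | Path) -> None:
    bio = [
        BioSeqRecord(Seq(r.sequence), id=name, description="")
        for name, r in sorted(records.items())
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_pairs(
    path: str | Path,
    peptides: dict[str, SequenceRecord] | None = None,
    proteins: dict[str, SequenceRecord] | None = None,
) -> InteractionTable:
    """Parse a pair-table TSV; malformed rows are reported with line numbers."""
    pairs: list[PairRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (3, 4):
                raise InvalidInputError(f"{path}:{lineno}: expected 3-4 columns, got {len(fields)}")
            pep_id, pro_id, label_s = fields[:3]
            try:
                label = int(label_s)
            except ValueError as exc:
                raise InvalidInputError(f"{path}:{lineno}: bad label {label_s!r}") from exc
            if label not in (0, 1):
                raise InvalidInputError(f"{path}:{lineno}: label must be 0/1")
            bv = None
            if len(fields) == 4 and fields[3] not in ("-", ""):
                try:
                    bv = np.array([int(x) for x in fields[3].split(",")], dtype=np.int64)
                except ValueError as exc:
                    raise InvalidInputError(f"{path}:{lineno}: bad binding vector") from exc
                if np.any((bv != 0) & (bv != 1)):
                    raise InvalidInputError(f"{path}:{lineno}: binding vector must be 0/1")
            pairs.append(PairRecord(pep_id, pro_id, label, bv))
    table = InteractionTable(pairs, dict(peptides or {}), dict(proteins or {}))
    table.validate()
    return table


def write_pairs(table: InteractionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in table.pairs:
            bv = (
                ",".join(str(int(x)) for x in rec.binding_vector)
                if rec.binding_vector is not None
                else "-"
            )
            fh.write(f"{rec.peptide_id}\t{rec.protein_id}\t{rec.label}\t{bv}\n")


# ---------------------------------------------------------------------------
# Feature manifest


def read_manifest_providers(manifest_path: str | Path) -> FeatureProviders:
    """Providers backed by sidecar files listed in a manifest TSV.

    Manifest columns: ``seq_id  pssm_path  ss_path  disorder_path`` (``-`` for
    absent); relative paths resolve against the manifest's directory.
    """
    base = Path(manifest_path).parent
    entries: dict[str, dict[str, Path | None]] = {}
    with open(manifest_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise InvalidInputError(f"{manifest_path}:{lineno}: expected 4 columns")
            sid, pssm, ss, dis = fields
            entries[sid] = {
                "pssm": base / pssm if pssm != "-" else None,
                "ss": base / ss if ss != "-" else None,
                "disorder": base / dis if dis != "-" else None,
            }

    stub = FeatureProviders()

    def _pssm(rec: SequenceRecord) -> np.ndarray:
        p = entries.get(rec.id, {}).get("pssm")
        if p is None:
            return stub.pssm_provider(rec)
        mat = np.loadtxt(p, ndmin=2)
        if mat.shape != (len(rec), 20):
            raise ProviderError(f"{p}: PSSM shape {mat.shape} != {(len(rec), 20)}")
        return mat

    def _ss(rec: SequenceRecord) -> str:
        p = entries.get(rec.id, {}).get("ss")
        if p is None:
            return stub.ss_provider(rec)
        return Path(p).read_text().strip()

    def _disorder(rec: SequenceRecord) -> np.ndarray:
        p = entries.get(rec.id, {}).get("disorder")
        if p is None:
            return stub.disorder_provider(rec)
        mat = np.loadtxt(p, ndmin=2)
        if mat.shape != (len(rec), 3):
            raise ProviderError(f"{p}: disorder shape {mat.shape} != {(len(rec), 3)}")
        return mat

    return FeatureProviders(pssm_provider=_pssm, ss_provider=_ss, disorder_provider=_disorder)


# ---------------------------------------------------------------------------
# Checkpoints


def save_checkpoint(params: ModelParams, path: str | Path) -> None:
    """Single-file checkpoint: JSON architecture header + raw weight arrays."""
    buf = _io.BytesIO()
    np.savez(buf, **params.arrays)
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_STORED) as zf:
        zf.writestr("arch.json", json.dumps(params.arch.to_dict()))
        zf.writestr("weights.npz", buf.getvalue())


def load_checkpoint(path: str | Path) -> ModelParams:
    with zipfile.ZipFile(path) as zf:
        arch = ArchitectureConfig.from_dict(json.loads(zf.read("arch.json")))
        with zf.open("weights.npz") as fh:
            npz = np.load(_io.BytesIO(fh.read()))
            arrays = {k: npz[k] for k in npz.files}
    return ModelParams(arch, arrays)


def write_loss_history(history, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch\tloss_pair\tloss_pep\tloss_total\n")
        for rep in history:
            fh.write(f"{rep.epoch}\t{rep.loss_pair:.6f}\t{rep.loss_pep:.6f}\t{rep.loss_total:.6f}\n")
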