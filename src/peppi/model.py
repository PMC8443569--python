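"""High-level modelling interface.

`PeptideProteinInteractionModel` is built from an interaction table (pairs,
labels, optional residue labels) plus sequence records; `fit()` trains the
network and returns a `PeppiResults` object carrying the fitted parameters,
the loss history, evaluation metrics and a `summary()` table. Prediction on
new tables and checkpoint round-trips hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .curation import InteractionTable
from .evaluation import MetricsReport, evaluate
from .exceptions import InvalidInputError
from .featurization import (
    DEFAULT_PROTEIN_PAD,
    MAX_PEPTIDE_LEN,
    FeatureProfile,
    FeatureProviders,
    build_profile,
)
from .network import ArchitectureConfig, ModelParams, PairSample, TINY_ARCH
from .training import StackedDataset, TrainConfig, TrainingState, predict_batch, train


def build_samples(
    table: InteractionTable,
    providers: FeatureProviders | None = None,
    protein_pad: int | None = None,
    profile_cache: dict[str, FeatureProfile] | None = None,
) -> list[PairSample]:
    """Featurize every pair in a table into network-ready samples.

    Profiles are built once per unique sequence; proteins are padded to the
    longest protein in the table (capped at the default protein pad length).
    """
    providers = providers or FeatureProviders()
    if protein_pad is None:
        longest = max(len(r) for r in table.proteins.values() if r is not None)
        protein_pad = min(longest, DEFAULT_PROTEIN_PAD)
    cache = profile_cache if profile_cache is not None else {}

    def profile_of(seq_id: str, role: str) -> FeatureProfile:
        if seq_id not in cache:
            rec = (table.peptides if role == "peptide" else table.proteins).get(seq_id)
            if rec is None:
                raise InvalidInputError(f"no sequence for id {seq_id}")
            pad = MAX_PEPTIDE_LEN if role == "peptide" else protein_pad
            cache[seq_id] = build_profile(rec, providers, pad_len=pad)
        return cache[seq_id]

    samples = []
    for rec in table.pairs:
        samples.append(
            PairSample(
                peptide=profile_of(rec.peptide_id, "peptide"),
                protein=profile_of(rec.protein_id, "protein"),
                label=rec.label,
                binding_vector=rec.binding_vector,
            )
        )
    return samples


@dataclass
class PeppiResults:
    """Fitted parameters plus diagnostics from one training run."""

    model: "PeptideProteinInteractionModel"
    params: ModelParams
    history: list = field(default_factory=list)
    train_metrics: MetricsReport | None = None

    def predict(
        self, table: InteractionTable | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Eval-mode (pair probabilities, residue probability matrix)."""
        if table is None:
            data = self.model.data
        else:
            data = StackedDataset.from_samples(
                build_samples(table, self.model.providers, self.model.protein_pad)
            )
        return predict_batch(data, self.params)

    def evaluate_on(self, table: InteractionTable | None = None) -> MetricsReport:
        data = (
            self.model.data
            if table is None
            else StackedDataset.from_samples(
                build_samples(table, self.model.providers, self.model.protein_pad)
            )
        )
        probs, res = predict_batch(data, self.params)
        has_res = data.res_masks.sum() > 0
        return evaluate(
            data.pair_labels,
            probs,
            data.res_labels if has_res else None,
            res if has_res else None,
            data.res_masks if has_res else None,
        )

    def save(self, path: str | Path) -> None:
        from .io import save_checkpoint

        save_checkpoint(self.params, path)

    def summary(self) -> str:
        lines = [
            "Peptide-protein interaction model",
            "=" * 46,
            f"parameters:        {self.params.n_parameters()}",
            f"epochs trained:    {len(self.history)}",
        ]
        if self.history:
            last = self.history[-1]
            lines += [
                f"final loss_pair:   {last.loss_pair:.4f}",
                f"final loss_pep:    {last.loss_pep:.4f}",
                f"final loss_total:  {last.loss_total:.4f}",
            ]
        if self.train_metrics is not None:
            m = self.train_metrics
            lines += [
                f"train pair AUC:    {m.pair_auc:.4f}",
                f"train pair AUPR:   {m.pair_aupr:.4f}",
            ]
            if m.mean_residue_auc is not None:
                lines += [
                    f"train residue AUC: {m.mean_residue_auc:.4f}",
                    f"train residue MCC: {m.mcc:.4f}",
                ]
        return "\n".join(lines)


class PeptideProteinInteractionModel:
    """Joint pair-interaction / binding-residue model over an interaction table."""

    def __init__(
        self,
        table: InteractionTable,
        arch: ArchitectureConfig = TINY_ARCH,
        providers: FeatureProviders | None = None,
        protein_pad: int | None = None,
    ):
        table.validate()
        self.table = table
        self.arch = arch
        self.providers = providers or FeatureProviders()
        if protein_pad is None:
            longest = max(len(r) for r in table.proteins.values() if r is not None)
            protein_pad = min(longest, DEFAULT_PROTEIN_PAD)
        self.protein_pad = protein_pad
        self.data = StackedDataset.from_samples(
            build_samples(table, self.providers, self.protein_pad)
        )

    @classmethod
    def from_files(
        cls,
        pair_tsv: str | Path,
        peptide_fasta: str | Path,
        protein_fasta: str | Path,
        arch: ArchitectureConfig = TINY_ARCH,
        manifest: str | Path | None = None,
    ) -> "PeptideProteinInteractionModel":
        from .io import read_fasta, read_manifest_providers, read_pairs

        peptides = read_fasta(peptide_fasta, "peptide")
        proteins = read_fasta(protein_fasta, "protein")
        table = read_pairs(pair_tsv, peptides, proteins)
        providers = read_manifest_providers(manifest) if manifest else None
        return cls(table, arch, providers)

    def fit(
        self,
        cfg: TrainConfig | None = None,
        init: ModelParams | None = None,
        evaluate_training_set: bool = True,
    ) -> PeppiResults:
        cfg = cfg or TrainConfig()
        state: TrainingState = train(self.data, self.arch, cfg, init=init)
        results = PeppiResults(model=self, params=state.params, history=state.history)
        if evaluate_training_set:
            results.train_metrics = results.evaluate_on()
        return results
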