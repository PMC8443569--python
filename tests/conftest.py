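import numpy as np
import pytest

from peppi.featurization import FeatureProviders, SequenceRecord, build_profile
from peppi.model import build_samples
from peppi.network import ArchitectureConfig, init_params
from peppi.synthetic import SyntheticConfig, generate_dataset
from peppi.training import StackedDataset


@pytest.fixture(scope="session")
def micro_arch():
    """Smallest architecture that exercises every component."""
    return ArchitectureConfig(
        embed_dim=3,
        conv_filters=(4, 4, 5),
        conv_kernels=(3, 3, 3),
        attention_dim=3,
        fc_sizes=(6, 4),
        dropout=0.0,
    )


@pytest.fixture(scope="session")
def micro_params(micro_arch):
    return init_params(micro_arch, seed=5)


@pytest.fixture(scope="session")
def tiny_table():
    """Small motif dataset with short proteins: 8 positives, 1:2 negatives."""
    cfg = SyntheticConfig(
        n_positives=8, negative_ratio=2, seed=7,
        peptide_len_range=(6, 15), protein_len_range=(51, 70),
    )
    table, truth = generate_dataset(cfg)
    return table, truth


@pytest.fixture(scope="session")
def tiny_data(tiny_table):
    table, _ = tiny_table
    return StackedDataset.from_samples(build_samples(table))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def peptide_record():
    return SequenceRecord("pep1", "peptide", "ACDEFGHIKL")


@pytest.fixture(scope="session")
def protein_record():
    return SequenceRecord("pro1", "protein", "ACDEFGHIKLMNPQRSTVWY" * 3)


@pytest.fixture(scope="session")
def peptide_profile(peptide_record):
    return build_profile(peptide_record, FeatureProviders(seed=0), pad_len=50)


@pytest.fixture(scope="session")
def protein_profile(protein_record):
    return build_profile(protein_record, FeatureProviders(seed=0), pad_len=80)
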