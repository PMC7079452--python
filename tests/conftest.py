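import numpy as np
import pytest

from charqsar.augmentation import AugmentationPolicy, augment_qsar_dataset
from charqsar.canonicalizer import TransformerConfig, build_canonicalizer
from charqsar.qsar_textcnn import CnnHeadConfig, QsarModel, train_qsar
from charqsar.synthetic_fixtures import (GrammarOracle, PlantedProperty,
                                         ToyLibrarySpec, generate_toy_library,
                                         make_planted_dataset)
from charqsar.tokenizer_io import default_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture(scope="session")
def grammar_oracle():
    return GrammarOracle()


@pytest.fixture(scope="session")
def rdkit_oracle():
    from charqsar.augmentation import RDKitOracle
    return RDKitOracle()


@pytest.fixture(scope="session")
def toy_library():
    spec = ToyLibrarySpec(n_molecules=60, max_heavy_atoms=6, seed=5)
    return generate_toy_library(spec)


@pytest.fixture(scope="session")
def tiny_config():
    return TransformerConfig(n_layers=1, n_heads=4, d_model=32, d_ff=64,
                             dropout=0.0, max_len=40)


@pytest.fixture(scope="session")
def tiny_encoder(tiny_config):
    """Randomly initialized (untrained) encoder: enough for shape,
    determinism and relevance-conservation tests."""
    return build_canonicalizer(tiny_config, seed=3)


@pytest.fixture(scope="session")
def small_head_config():
    return CnnHeadConfig(
        kernel_sizes=(1, 2, 3, 5),
        filter_counts=(8, 12, 12, 8),
        task="regression",
        learning_rate=1e-3,
        max_epochs=8,
        patience=3,
        batch_size=32,
        seed=0,
    )


@pytest.fixture(scope="session")
def trained_qsar_model(tiny_encoder, grammar_oracle, small_head_config):
    """Small regression model trained on a planted halogen-count rule;
    shared by LRP/attribution/consensus tests."""
    lib = generate_toy_library(ToyLibrarySpec(n_molecules=40, max_heavy_atoms=6, seed=21))
    planted = PlantedProperty(rule="halogen_count", betas=(2.0, 0.0), noise_sd=0.1)
    records, _ = make_planted_dataset(lib, planted, seed=0)
    rows = augment_qsar_dataset(records, AugmentationPolicy(n_augment=3, seed=0),
                                grammar_oracle)
    return train_qsar(rows, tiny_encoder, small_head_config)


@pytest.fixture
def untrained_qsar_model(tiny_encoder, small_head_config):
    from charqsar.qsar_textcnn import build_head
    head = build_head(small_head_config, tiny_encoder.config.d_model)
    return QsarModel(encoder=tiny_encoder, head=head, config=small_head_config)
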