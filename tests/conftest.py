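import numpy as np
import pytest

from plgscore.featurize import FeatureConfig, featurize_complex
from plgscore.model import ModelConfig, ScoringModel
from plgscore.synthetic import make_toy_ligand, make_toy_protein


SMALL_MODEL = ModelConfig(
    node_hidden=32, edge_hidden=16, attention_heads=2, gmlp_ffn=256, seed=11
)


@pytest.fixture(scope="session")
def toy_protein():
    return make_toy_protein(8, seed=1)


@pytest.fixture(scope="session")
def toy_ligand(toy_protein):
    # centered against the helix so every heavy atom is in contact range
    return make_toy_ligand("ring6_tail", center=(4.5, 0.0, 5.25), pose_id="native")


@pytest.fixture(scope="session")
def toy_graphs(toy_protein, toy_ligand):
    return featurize_complex(toy_protein, toy_ligand, toy_ligand, FeatureConfig())


@pytest.fixture(scope="session")
def small_model():
    model = ScoringModel(SMALL_MODEL)
    model.set_training(False)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
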