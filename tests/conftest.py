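import warnings

import numpy as np
import pytest

from masmddi import TrainConfig, generate_corpus
from masmddi.model import DDIModel

# split/metric helpers warn on degenerate inputs; tests assert behaviour,
# not silence
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def tiny_corpus():
    """12 drugs, 2 relations, 20 positive triples; noise-free."""
    return generate_corpus(n_drugs=12, n_relations=2, n_triples=20, seed=3)


@pytest.fixture(scope="session")
def small_config():
    return TrainConfig(n_layers=2, hidden_dim=8, epochs=2, batch_size=16, seed=9)


@pytest.fixture()
def small_model(tiny_corpus, small_config):
    """Untrained model over the tiny corpus (params seeded, not fitted)."""
    model = DDIModel(tiny_corpus.triples, tiny_corpus.drug_map,
                     config=small_config, n_relations=2,
                     known_positives=tiny_corpus.rule_closure())
    model.init_params()
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
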