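import numpy as np
import pytest

from protmol.encoder import JointEncoderConfig, MultimodalTransformer
from protmol.pipeline import default_provider
from protmol.splits import SplitSpec, make_split
from protmol.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_cfg():
    return SyntheticConfig(n_proteins=24, n_molecules=18, n_pairs=120, seed=7)


@pytest.fixture(scope="session")
def tiny_data(tiny_cfg):
    data, manifest = generate_dataset(tiny_cfg)
    return data, manifest


@pytest.fixture(scope="session")
def tiny_provider(tiny_cfg):
    return default_provider(tiny_cfg, d_p=32, d_s=16)


@pytest.fixture(scope="session")
def tiny_split(tiny_data):
    data, _ = tiny_data
    return make_split(data, SplitSpec(scenario="random", n_repeats=1, seed=7))[0]


@pytest.fixture(scope="session")
def tiny_encoder_config():
    return JointEncoderConfig.scaled_down(
        hidden_dim=32, num_heads=2, head_dim=16, epochs=4, seed=7
    )


@pytest.fixture(scope="session")
def trained_encoder(tiny_data, tiny_provider, tiny_split, tiny_encoder_config):
    data, _ = tiny_data
    train = data.subset(tiny_split.train)
    val = data.subset(tiny_split.val)
    enc = MultimodalTransformer.from_config(tiny_encoder_config, task="regression")
    return enc.fit(train, tiny_provider, val)
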