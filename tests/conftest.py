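import numpy as np
import pytest

from rxnrl.chemio import parse_reaction
from rxnrl.forward_model import MLEConfig, ModelDims, Seq2SeqPolicy, Vocab, train_mle

TINY_REACTIONS = [
    "Cc1ccccc1.BrBr>>Cc1ccccc1Br",
    "Oc1ccccc1.CI>>COc1ccccc1",
    "Cc1ccncc1.ClCl>>Cc1ccncc1Cl",
    "CCc1cccnc1.BrBr>>CCc1cccnc1Br",
    "Nc1ccccc1.CC(=O)Cl>>CC(=O)Nc1ccccc1",
    "N#Cc1ccccc1.[H][H]>>NCc1ccccc1",
    "Oc1ccncc1.CI>>COc1ccncc1",
    "Cc1ccco1.BrBr>>Cc1ccc(Br)o1",
    "CCc1ccccc1.ClCl>>CCc1ccccc1Cl",
    "Oc1cccnc1.CI>>COc1cccnc1",
]


@pytest.fixture(scope="session")
def tiny_reactions():
    return [parse_reaction(s) for s in TINY_REACTIONS]


@pytest.fixture(scope="session")
def tiny_vocab(tiny_reactions):
    return Vocab.from_texts([r.serialize() for r in tiny_reactions])


@pytest.fixture(scope="session")
def tiny_dims():
    return ModelDims(d_model=32, n_heads=2, n_layers=1, d_ff=64, max_len=64)


@pytest.fixture(scope="session")
def memorized_policy(tiny_reactions, tiny_vocab, tiny_dims):
    """A policy overfit to the ten tiny reactions (capacity sanity baseline)."""
    policy = Seq2SeqPolicy(tiny_vocab, tiny_dims, seed=0)
    policy, _ = train_mle(
        policy, tiny_reactions, MLEConfig(epochs=150, batch_size=10, lr=3e-3, seed=0)
    )
    return policy


@pytest.fixture
def rng():
    return np.random.default_rng(0)
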