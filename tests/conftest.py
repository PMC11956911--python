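import numpy as np
import pytest

from attnrank import FixtureSpec, random_attention_stack
from attnrank.plm_adapter import ResidueView


def make_view(n=20, L=4, d=8, seed=0, attention=None, embeddings=None, cls=None):
    """Residue view over a synthetic attention stack (helper, not a fixture)."""
    spec = FixtureSpec(n=n, L=L, d=d, seed=seed)
    if attention is None:
        attention = random_attention_stack(spec)
    if embeddings is None:
        embeddings = np.random.default_rng(seed).standard_normal((n, d))
    return ResidueView(
        embeddings=embeddings,
        attention=attention,
        sequence="A" * n,
        cls_embedding=cls,
        sequence_id=f"synthetic_{n}_{seed}",
    )


@pytest.fixture
def small_view():
    return make_view(n=12, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
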