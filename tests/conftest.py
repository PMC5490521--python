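import pytest
from hypothesis import settings

from standfood import FixtureSpec, generate_vocabulary, train_ensemble

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_vocab():
    """The default 400-record synthetic vocabulary (seed 7)."""
    return generate_vocabulary(seed=7)


@pytest.fixture(scope="session")
def small_vocab():
    """A quick-to-train 120-record vocabulary with the default skew."""
    return generate_vocabulary(
        FixtureSpec(n_raw=56, n_derivative=40, n_simple=16, n_aggregated=8, seed=7)
    )


@pytest.fixture(scope="session")
def small_model(small_vocab):
    return train_ensemble(small_vocab, seed=7)
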