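import numpy as np
import pytest

from dbpred.fixtures import FixtureSpec, generate_fixture_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Balanced 40-protein synthetic dataset with moderate class signal."""
    spec = FixtureSpec(
        n_positive=20, n_negative=20, length_range=(50, 80), seed=7,
        signal_strength=0.5, ss_bias=0.3,
    )
    return generate_fixture_dataset(spec)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The same dataset written to disk in all three external formats."""
    out = tmp_path_factory.mktemp("fixture_data")
    spec = FixtureSpec(
        n_positive=20, n_negative=20, length_range=(50, 80), seed=7,
        signal_strength=0.5, ss_bias=0.3,
    )
    generate_fixture_dataset(spec, out_dir=out)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)
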