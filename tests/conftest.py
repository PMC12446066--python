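import numpy as np
import pytest

from clemreg import synthgen


@pytest.fixture(scope="session")
def small_spec():
    """A compact paired-volume spec: 10 mitochondria, 3 targets, fast to build."""
    return synthgen.FixtureSpec(
        seed=7,
        shape=(48, 192, 192),
        n_mito=10,
        n_targets=3,
        mito_major_semi_nm=(200.0, 350.0),
        mito_minor_semi_nm=(100.0, 160.0),
        target_diameter_nm=(300.0, 600.0),
        min_gap_nm=250.0,
    )


@pytest.fixture(scope="session")
def small_fixture(small_spec):
    return synthgen.generate_fixture(small_spec)


@pytest.fixture(scope="session")
def standard_fixture():
    """The default study-condition fixture (40 instances, rigid truth)."""
    return synthgen.generate_fixture(synthgen.FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def fixture_dir(small_fixture, tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture")
    synthgen.write_fixture(small_fixture, d)
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
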