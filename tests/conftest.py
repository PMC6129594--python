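import numpy as np
import pytest

from hemiasym import SyntheticSpec, make_fixtures, read_cohort


@pytest.fixture(scope="session")
def small_spec():
    """A fast 10-regions-per-hemisphere world for unit tests."""
    return SyntheticSpec(
        n_patients=5, n_controls=6, n_regions_per_hemisphere=10,
        edge_density=0.4, clinical_link=None, seed=7,
    )


@pytest.fixture(scope="session")
def fixture_cohort_dir(tmp_path_factory):
    """The deterministic miniature cohort on disk."""
    out = tmp_path_factory.mktemp("fixture") / "cohort"
    return make_fixtures(out)


@pytest.fixture(scope="session")
def fixture_cohort(fixture_cohort_dir):
    return read_cohort(fixture_cohort_dir)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_symmetric_fa(rng, n, density=0.4):
    """Random symmetric FA-like adjacency with zero diagonal."""
    mask = np.triu(rng.random((n, n)) < density, 1)
    w = np.zeros((n, n))
    w[mask] = rng.uniform(0.05, 1.0, size=mask.sum())
    return w + w.T
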