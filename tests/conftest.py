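import numpy as np
import pytest

from bootbin.synthetic import CommunitySpec, generate_community


@pytest.fixture(scope="session")
def clean_community():
    """Default 5-genome assembly-like community with ground truth."""
    records, truth = generate_community(CommunitySpec.contigs(seed=7))
    return records, truth


@pytest.fixture(scope="session")
def small_community():
    """Cheap 3-genome community for pipeline-level unit tests."""
    spec = CommunitySpec.contigs(n_genomes=3, fragments_per_genome=60, seed=3)
    records, truth = generate_community(spec)
    return records, truth


@pytest.fixture(scope="session")
def three_clouds():
    """Three well-separated isotropic Gaussian clouds in 512-D."""
    rng = np.random.default_rng(42)
    centers = rng.normal(size=(3, 512)) * 20.0
    X = np.vstack([c + rng.normal(size=(40, 512)) for c in centers])
    y = np.repeat([0, 1, 2], 40)
    return X, y
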