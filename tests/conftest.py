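import numpy as np
import pytest

from cortodeconv import flat_hierarchy, synth


@pytest.fixture(scope="session")
def small_truth():
    """200-gene, 5-type ground truth with moderate dropout."""
    return synth.make_ground_truth(n_genes=200, n_types=5, seed=7)


@pytest.fixture(scope="session")
def small_expression(small_truth):
    """Noise-free expression tensor from the small truth bundle."""
    return synth.make_expression(
        small_truth.transcriptomes, small_truth.densities, noise_cv=0.0, seed=7
    )


@pytest.fixture(scope="session")
def small_hierarchy(small_truth):
    return flat_hierarchy(small_truth.transcriptomes.type_ids)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
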