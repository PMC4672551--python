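import numpy as np
import pytest

from ecomemory import CommunityMatrix, EvoConfig, GrowthParams, uniform_community


@pytest.fixture
def growth_single():
    return GrowthParams(m=[0.5], k=[10.0])


@pytest.fixture
def single_species_matrix():
    return CommunityMatrix(np.array([[-1.0]]))


@pytest.fixture
def small_config():
    """A deliberately tiny configuration for fast loop tests."""
    return EvoConfig.desk_scale(N=30, tau=600, probe_tau=2000, n_generations=10,
                                snapshot_stride=5)


@pytest.fixture
def perturbed_3x3():
    """3x3 symmetric competitive matrix off its conserved budgets."""
    omega = np.array(
        [
            [-1.0, -0.3, -0.2],
            [-0.3, -1.0, -0.1],
            [-0.2, -0.1, -1.0],
        ]
    )
    return CommunityMatrix(omega, Q=np.full(3, -0.4))
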