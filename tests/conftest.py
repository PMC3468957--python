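import numpy as np
import pytest

from rsnfuse.group import group_ica_fit
from rsnfuse.synthetic import (
    LinkedSimulationSpec,
    PhantomStudySpec,
    generate_linked_dataset,
    generate_phantom_study,
)

# the unbalanced-dimension validation, scaled to 2,000 voxels so a fit
# runs in well under a second; sample count and component counts are the
# study's (100 samples, 8 + 4 components)
SIM_KW = dict(n_feat1=2000)

# compact phantom for unit tests: the full emulated acquisition
# (20^3 grid, 228 time points) is exercised in the dedicated
# spec-conformance tests, not in every fixture
PHANTOM_KW = dict(grid=(14, 14, 14), n_timepoints=60)


@pytest.fixture(scope="session")
def linked_dataset():
    spec = LinkedSimulationSpec(links=[(0, 0, 0.8)], **SIM_KW)
    return generate_linked_dataset(spec, seed=5)


@pytest.fixture(scope="session")
def phantom_study():
    spec = PhantomStudySpec(planted_rho=0.85, **PHANTOM_KW)
    return spec, *generate_phantom_study(spec, seed=3)


@pytest.fixture(scope="session")
def phantom_decomposition(phantom_study):
    spec, vols, table, truth = phantom_study
    subjects = [v.reshape(-1, v.shape[-1]).T for v in vols]
    dec = group_ica_fit(subjects, k_subject=10, k_group=6, seed=0)
    return dec, spec, table, truth


@pytest.fixture
def laplace_mixture():
    """3 unit-variance Laplacian sources through a random 6 x 3 mixing."""
    rng = np.random.default_rng(42)
    S = rng.laplace(size=(3, 5000))
    S = (S - S.mean(1, keepdims=True)) / S.std(1, keepdims=True)
    A = rng.standard_normal((6, 3))
    return A, S, A @ S
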