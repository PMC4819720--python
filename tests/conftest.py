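import numpy as np
import pytest

from taylornet import (
    ConnectivityMatrix,
    MatrixStack,
    SyntheticSpec,
    gen_stack,
    plant_target,
)


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """P=20, D=3, noiseless: exact recovery territory."""
    return SyntheticSpec(P=20, D=3, noise_sd=0.0, seed=101)


@pytest.fixture(scope="session")
def small_stack(small_spec) -> MatrixStack:
    return gen_stack(small_spec)


@pytest.fixture(scope="session")
def small_target(small_spec, small_stack) -> ConnectivityMatrix:
    return plant_target(small_stack, small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_target(stack: MatrixStack, rng: np.random.Generator, scale: float = 0.2):
    """A symmetric target independent of the stack."""
    p = stack.n_regions
    iu = np.triu_indices(p, 1)
    v = np.zeros((p, p))
    v[iu] = rng.normal(0.0, scale, size=iu[0].size)
    v = v + v.T
    return ConnectivityMatrix(
        v, metric="generic", region_labels=stack.region_labels, check_range=False
    )
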