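import numpy as np
import pytest

from rsdiag.phantom import PhantomSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Small noiseless 4-area cohort used by decomposition/atlas tests."""
    return PhantomSpec(
        grid_shape=(20, 20, 10),
        n_timepoints=100,
        tr_seconds=2.0,
        n_areas=4,
        noise_sigma=0.0,
        n_asd=2,
        n_td=2,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return simulate_cohort(small_spec)


@pytest.fixture(scope="session")
def effect_spec() -> PhantomSpec:
    """3-of-10 affected areas, strong effect, 40 subjects."""
    return PhantomSpec(
        grid_shape=(20, 20, 10),
        n_timepoints=100,
        tr_seconds=2.0,
        n_areas=10,
        affected_areas=frozenset({2, 5, 9}),
        effect_size=3.0,
        noise_sigma=0.5,
        n_asd=20,
        n_td=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def effect_dataset(effect_spec):
    """Feature dataset of the effect cohort (ground-truth time courses)."""
    from rsdiag.pipeline import phantom_dataset

    dataset, truth = phantom_dataset(effect_spec, via_decomposition=False)
    return dataset, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
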