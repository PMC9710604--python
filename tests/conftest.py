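import numpy as np
import pytest

from recombat import (
    DesignSpec,
    ExpressionMatrix,
    SampleMetadata,
    SimulationConfig,
    simulate,
)


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(7)
    return ExpressionMatrix(
        rng.normal(size=(5, 7)),
        [f"s{i}" for i in range(5)],
        [f"g{k}" for k in range(7)],
    )


@pytest.fixture
def toy_meta():
    """4 samples, 2 batches, one binary covariate."""
    return SampleMetadata(
        sample_ids=["s0", "s1", "s2", "s3"],
        columns={"batch": ["b1", "b1", "b2", "b2"], "cond": ["p", "q", "p", "q"]},
        batch_column="batch",
    )


@pytest.fixture
def toy_spec():
    return DesignSpec(batch_column="batch", desired_columns=["cond"])


@pytest.fixture(scope="session")
def sim_default():
    """The default simulated study: 500 samples, 10 batches, 10 Zero-Hops."""
    return simulate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def sim_small():
    """A cheaper instance for tests that refit models repeatedly."""
    return simulate(
        SimulationConfig(
            n_samples=200, n_batches=4, n_zero_hops=8, n_genes=60, seed=5
        )
    )


@pytest.fixture(scope="session")
def sim_singular():
    return simulate(
        SimulationConfig(
            n_samples=200,
            n_batches=5,
            n_zero_hops=8,
            n_genes=50,
            singular_design=True,
            seed=13,
        )
    )
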