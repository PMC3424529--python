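import numpy as np
import pytest

from swarmsvm import ExpressionDataset, PsoConfig, generate_synthetic_dataset


@pytest.fixture
def separable_dataset():
    """Strongly separable synthetic data: 20 samples, 12 genes, 3 planted."""
    ds, truth = generate_synthetic_dataset(
        n_samples=20, n_genes=12, n_informative=3, effect_size=5.0, seed=11
    )
    return ds, truth


@pytest.fixture
def tiny_dataset():
    """Hand-built 4-sample, 2-gene dataset, one clear discriminative gene."""
    return ExpressionDataset(
        matrix=[[0.0, 1.0], [0.2, 0.0], [5.0, 0.5], [5.2, 1.5]],
        labels=[1, 1, -1, -1],
        gene_ids=["gA", "gB"],
        sample_ids=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def fast_pso():
    return PsoConfig(swarm_size=5, max_iterations=4, seed=0)


class ConstantRng:
    """Stub RNG returning a fixed value; freezes the stochastic PSO update."""

    def __init__(self, value):
        self.value = value

    def random(self, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)


@pytest.fixture
def constant_rng():
    return ConstantRng
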