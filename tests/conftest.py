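import numpy as np
import pytest
from hypothesis import settings

from gwrf.datagen import CohortConfig, simulate_cohort
from gwrf.forest import EvolutionConfig, GeneticWeightedForest
from gwrf.fusion import FusedDataset, build_pair_dataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """120-participant AD/HC cohort with 10 planted voxels, strong signal."""
    cfg = CohortConfig(
        group_sizes={"HC": 60, "AD": 60},
        n_voxels=200,
        n_informative_voxels=10,
        voxel_effect=2.0,
        seed=123,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def fused_pair(small_cohort) -> FusedDataset:
    c = small_cohort
    return build_pair_dataset(
        c.voxels[c.group_rows("AD")],
        c.voxels[c.group_rows("HC")],
        "AD-HC",
        ids_a=c.ids[c.group_rows("AD")],
        ids_b=c.ids[c.group_rows("HC")],
    )


@pytest.fixture(scope="session")
def separable_dataset() -> FusedDataset:
    """Tiny dataset separable on feature 0 only."""
    rng = np.random.default_rng(7)
    n = 40
    x = rng.standard_normal((n, 8))
    labels = np.repeat([1, -1], n // 2)
    x[:, 0] = labels * 3.0 + 0.1 * rng.standard_normal(n)
    return FusedDataset(x, labels, np.arange(n).astype(str), np.ones(n), "toy")


@pytest.fixture(scope="session")
def fitted_results(fused_pair):
    config = EvolutionConfig(n_trees=12, group_size=4, generations=2, seed=5)
    return GeneticWeightedForest(fused_pair, config).fit()
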