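import numpy as np
import pandas as pd
import pytest

from exprmap import DataMap, ExpressionMatrix, FilterCriteria, create_map
from exprmap.simulate import SimulationSpec, simulate_counts


@pytest.fixture
def frozen_clock():
    return lambda: "2024-01-01T00:00:00+00:00"


@pytest.fixture
def worked_counts():
    """The 3-gene / 2-sample matrix behind the hand-worked size-factor values."""
    return ExpressionMatrix(
        pd.DataFrame([[2, 8], [4, 16], [0, 5]], index=["g1", "g2", "g3"], columns=["A", "B"])
    )


@pytest.fixture
def small_simulated():
    spec = SimulationSpec(n_features=80, n_samples=8, n_spikes=4, de_frac=0.2, seed=7)
    return simulate_counts(spec)


@pytest.fixture
def chain_map(small_simulated, frozen_clock) -> DataMap:
    """A fixture map: root → normalize → filter_features → subset, plus a
    second branch and a merge node."""
    matrix, design, truth = small_simulated
    dmap = create_map(matrix, "raw", clock=frozen_clock)
    n1 = dmap.normalize_node(dmap.root_id, "median_ratio", min_detect_frac=0.5)
    n2 = dmap.filter_features_node(n1, FilterCriteria(min_count=1, min_samples=2))
    dmap.subset_node(n2, sample_ids=matrix.sample_ids[:4], label="first-half")
    left = dmap.subset_node(dmap.root_id, sample_ids=matrix.sample_ids[:4])
    right = dmap.subset_node(dmap.root_id, sample_ids=matrix.sample_ids[4:])
    dmap.merge_node([left, right], axis="samples", label="rejoined")
    return dmap


def random_counts(rng: np.random.Generator, nf: int, ns: int, zero_free: bool = False):
    vals = rng.integers(1 if zero_free else 0, 50, size=(nf, ns)).astype(float)
    if zero_free:
        vals += 1
    return ExpressionMatrix(
        pd.DataFrame(
            vals,
            index=[f"g{i}" for i in range(nf)],
            columns=[f"s{j}" for j in range(ns)],
        )
    )
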