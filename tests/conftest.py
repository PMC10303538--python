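import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from subcomm.containers import CommunityTable, DistanceMatrix
from subcomm.simulate import preset_config, simulate_dataset


@pytest.fixture
def three_tip_tree() -> TreeNode:
    """((A:1,B:1):0.5,C:1.5); — patristic d(A,B)=2, d(A,C)=d(B,C)=3."""
    return TreeNode.read(["((A:1,B:1):0.5,C:1.5);"])


@pytest.fixture
def small_table() -> CommunityTable:
    return CommunityTable(
        ["A", "B", "C"], ["s1", "s2"],
        np.array([[2.0, 1.0], [0.0, 1.0], [1.0, 0.0]]))


@pytest.fixture(scope="session")
def sim_dataset():
    """One 200-taxon, 19+25-sample survey under the filtering regime."""
    cfg = preset_config("filtering", seed=42, n_taxa=200, read_depth=10_000)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def sim_meta_groups(sim_dataset):
    _, _, meta, _ = sim_dataset
    return {g: sorted(meta.loc[meta["group"] == g, "sample_id"])
            for g in meta["group"].unique()}


def random_euclidean_dm(rng: np.random.Generator, n: int, dim: int = 5,
                        spread: float = 1.0) -> DistanceMatrix:
    """Distance matrix of iid Gaussian points (valid metric by construction)."""
    pts = rng.standard_normal((n, dim)) * spread
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix([f"s{i}" for i in range(n)], d)
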