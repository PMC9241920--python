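import numpy as np
import pandas as pd
import pytest
import skbio

from ecoassembly import OtuTable, EnvTable


@pytest.fixture
def three_taxon_tree() -> skbio.TreeNode:
    """((A:1,B:1):1,C:2); — d(A,B)=2, d(A,C)=d(B,C)=4."""
    return skbio.TreeNode.read(["((A:1,B:1):1,C:2);"])


@pytest.fixture
def small_table() -> OtuTable:
    data = pd.DataFrame(
        [[6, 2, 0], [2, 2, 0], [0, 0, 4]],
        index=["s1", "s2", "s3"],
        columns=["A", "B", "C"],
    )
    return OtuTable(data)


@pytest.fixture
def env_table() -> EnvTable:
    data = pd.DataFrame(
        {
            "temperature": [5.0, 7.0, 26.0, 26.5],
            "salinity": [28.0, 27.0, 22.0, 22.5],
        },
        index=["w1", "w2", "u1", "u2"],
    )
    grouping = pd.DataFrame(
        {"season": ["winter", "winter", "summer", "summer"],
         "site": ["s1", "s2", "s1", "s2"]},
        index=data.index,
    )
    return EnvTable(data, grouping)


def random_otu_table(rng: np.random.Generator, n_samples: int, n_taxa: int,
                     depth: int = 100) -> OtuTable:
    """Uniform-ish multinomial counts, every sample nonempty."""
    weights = rng.dirichlet(np.ones(n_taxa))
    counts = np.vstack([rng.multinomial(depth, weights) for _ in range(n_samples)])
    return OtuTable(pd.DataFrame(
        counts,
        index=[f"s{k}" for k in range(n_samples)],
        columns=[f"T{k}" for k in range(n_taxa)],
    ))
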