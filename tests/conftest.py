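import numpy as np
import pytest

from phyloturn.trees import Phylogeny


@pytest.fixture
def basic_tree() -> Phylogeny:
    """((A:1,B:1):1,(C:1,D:1):1) — the worked 4-tip example tree."""
    return Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260905)
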