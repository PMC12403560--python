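import numpy as np
import pytest

from regloss import FIXTURE_TREE_10, SpeciesTree
from regloss.simulate import make_fixture


@pytest.fixture(scope="session")
def fixture_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(FIXTURE_TREE_10)


@pytest.fixture(scope="session")
def mini_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle") / "mini"
    meta = make_fixture("mini", out, seed=42)
    return meta


def random_rooted_tree(n_leaves: int, rng: np.random.Generator) -> SpeciesTree:
    """Random bifurcating rooted tree by successive joins (test helper,
    independent of the package's own tree generator)."""
    parts = [f"L{i}" for i in range(n_leaves)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b})")
    return SpeciesTree.from_newick(parts[0] + ";")
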