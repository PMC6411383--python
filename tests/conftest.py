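import numpy as np
import pytest

from grasstraits.synthetic import SimConfig, assign_groups, simulate_study, simulate_yule_tree
from grasstraits.treeio import parse_newick, phylo_covariance


@pytest.fixture()
def three_tip():
    """((A:1,B:1):1,C:2) with its known covariance [[2,1,0],[1,2,0],[0,0,2]]."""
    tree = parse_newick("((A:1,B:1):1,C:2);")
    return tree, phylo_covariance(tree)


@pytest.fixture(scope="session")
def study():
    """A 42-tip study-shaped setup: tree, factorial groups, covariance."""
    tree = simulate_yule_tree(42, seed=7)
    groups = assign_groups(tree, SimConfig(seed=7))
    C = phylo_covariance(tree, list(groups.index))
    return tree, groups, C


@pytest.fixture(scope="session")
def bundle():
    return simulate_study(SimConfig(seed=3))


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures") / "bundle"
    bundle.write(out)
    return out
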