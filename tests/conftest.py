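import numpy as np
import pytest
from hypothesis import settings

from dodder import synthetic
from dodder.trees import Phylogeny

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_tree() -> Phylogeny:
    return synthetic.fixture_tree()


@pytest.fixture(scope="session")
def neo_states():
    return synthetic.fixture_neoxanthin_states()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def cherry() -> Phylogeny:
    return Phylogeny.from_newick("(A:1.0,B:1.0);")


@pytest.fixture(scope="session")
def three_tip() -> Phylogeny:
    return Phylogeny.from_newick("((A:0.3,B:0.3):0.7,C:1.0);")


@pytest.fixture(scope="session")
def four_tip() -> Phylogeny:
    return Phylogeny.from_newick("(((A:0.2,B:0.2):0.3,C:0.5):0.5,D:1.0);")


def random_rooted_tree(rng: np.random.Generator, n_tips: int, max_bl: float = 1.0) -> Phylogeny:
    """Random topology by sequential joining; random branch lengths."""
    import dendropy

    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for i in range(n_tips):
        leaf = dendropy.Node(taxon=taxa[i])
        leaf.edge.length = float(rng.uniform(0.05, max_bl))
        nodes.append(leaf)
    rng_order = list(nodes)
    while len(rng_order) > 2:
        i, j = sorted(rng.choice(len(rng_order), size=2, replace=False))
        a, b = rng_order[i], rng_order[j]
        joint = dendropy.Node()
        joint.edge.length = float(rng.uniform(0.05, max_bl))
        joint.add_child(a)
        joint.add_child(b)
        rng_order = [n for k, n in enumerate(rng_order) if k not in (i, j)] + [joint]
    for n in rng_order:
        tree.seed_node.add_child(n)
    return Phylogeny(tree)
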