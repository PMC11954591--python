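import numpy as np
import pandas as pd
import pytest

from phylocna import parse_newick
from phylocna.synth import PlantedSet, SimulationConfig, simulate_dataset


@pytest.fixture
def cherry():
    return parse_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def labeled_six_tip():
    # internal nodes labeled so ancestral estimates can be addressed
    return parse_newick(
        "(((A:1,B:1)ab:1,(C:1.5,D:0.5)cd:1)abcd:1,(E:2,F:2)ef:1);"
    )


def random_tree(n_tips: int, rng: np.random.Generator):
    """Random tree with exponential branch lengths (not ultrametric);
    independent of the package's Yule generator."""
    import dendropy

    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for i in range(n_tips):
        node = dendropy.Node(taxon=taxa[i])
        node.edge.length = float(rng.exponential(1.0)) + 0.05
        nodes.append(node)
    rng.shuffle(nodes)
    while len(nodes) > 2:
        a = nodes.pop(int(rng.integers(len(nodes))))
        b = nodes.pop(int(rng.integers(len(nodes))))
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = float(rng.exponential(1.0)) + 0.05
        nodes.append(parent)
    for node in nodes:
        tree.seed_node.add_child(node)
    text = tree.as_string(
        schema="newick", suppress_rooting=True,
        real_value_format_specifier=".17g",
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # these trees are not ultrametric
        return parse_newick(text)


@pytest.fixture
def small_dataset():
    """94-species null dataset (no planted effects) shared across tests."""
    config = SimulationConfig(n_species=94, n_orthogroups=120, seed=11)
    return simulate_dataset(config)


@pytest.fixture
def planted_dataset():
    """Dataset with a strongly planted 12-orthogroup malignancy-rate set."""
    config = SimulationConfig(
        n_species=94,
        n_orthogroups=200,
        seed=23,
        sets=[PlantedSet("planted", 12, "malignancy_rate", -0.05)],
        necropsy_range=(40, 120),
    )
    return simulate_dataset(config)
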