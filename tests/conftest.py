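import numpy as np
import pytest

from crabtree.network import AtomMapNetwork, Metabolite, Reaction


def _ident(n):
    return [[0, c] for c in range(1, n + 1)]


@pytest.fixture(scope="session")
def linear_chain():
    """S(ext) -> A -> B -> C -> sink, 3 carbons, identity maps."""
    net = AtomMapNetwork("linear_chain")
    net.add_metabolite(Metabolite("S", 3, "external", balanced=False))
    net.add_metabolite(Metabolite("OUT", 3, "external", balanced=False))
    for m in "ABC":
        net.add_metabolite(Metabolite(m, 3))
    net.add_reaction(Reaction("u", [("S", 1)], [("A", 1)], [_ident(3)]))
    net.add_reaction(Reaction("r1", [("A", 1)], [("B", 1)], [_ident(3)]))
    net.add_reaction(Reaction("r2", [("B", 1)], [("C", 1)], [_ident(3)]))
    net.add_reaction(Reaction("out", [("C", 1)], [("OUT", 1)], [_ident(3)]))
    net.substrate_label = {"S": [("100", 1.0)]}
    return net


@pytest.fixture(scope="session")
def condensation_net():
    """A(2C, 50% [1-13C]) + A -> D(4C): convolution test case."""
    net = AtomMapNetwork("condensation")
    net.add_metabolite(Metabolite("Aext", 2, "external", balanced=False))
    net.add_metabolite(Metabolite("A", 2))
    net.add_metabolite(Metabolite("D", 4))
    net.add_metabolite(Metabolite("OUT", 4, "external", balanced=False))
    net.add_reaction(Reaction("u", [("Aext", 1)], [("A", 1)], [_ident(2)]))
    net.add_reaction(Reaction("cond", [("A", 2)], [("D", 1)],
                              [[[0, 1], [0, 2], [1, 1], [1, 2]]]))
    net.add_reaction(Reaction("out", [("D", 1)], [("OUT", 1)], [_ident(4)]))
    net.substrate_label = {"Aext": [("10", 0.5), ("00", 0.5)]}
    return net


@pytest.fixture(scope="session")
def symmetric_net():
    """P(4C, [1-13C]) -> F(symmetric) -> M -> sink: orientation averaging."""
    net = AtomMapNetwork("symmetric")
    net.add_metabolite(Metabolite("P", 4, "external", balanced=False))
    net.add_metabolite(Metabolite("F", 4, symmetric=True))
    net.add_metabolite(Metabolite("M", 4))
    net.add_metabolite(Metabolite("OUT", 4, "external", balanced=False))
    net.add_reaction(Reaction("u", [("P", 1)], [("F", 1)], [_ident(4)]))
    net.add_reaction(Reaction("fm", [("F", 1)], [("M", 1)], [_ident(4)]))
    net.add_reaction(Reaction("out", [("M", 1)], [("OUT", 1)], [_ident(4)]))
    net.substrate_label = {"P": [("1000", 1.0)]}
    return net


@pytest.fixture(scope="session")
def branch_net():
    """Substrate splits into two pools with distinct carbon fates that
    merge again: the branch ratio is identifiable from labeling alone.

    S(2C, [1-13C]) -> A; A -> M (identity) vs A -> M (carbons swapped);
    M -> sink.  Enrichment of M carbon 1 equals the identity-branch
    fraction.
    """
    net = AtomMapNetwork("two_branch")
    net.add_metabolite(Metabolite("S", 2, "external", balanced=False))
    net.add_metabolite(Metabolite("A", 2))
    net.add_metabolite(Metabolite("M", 2))
    net.add_metabolite(Metabolite("OUT", 2, "external", balanced=False))
    net.add_reaction(Reaction("u", [("S", 1)], [("A", 1)], [_ident(2)]))
    net.add_reaction(Reaction("keep", [("A", 1)], [("M", 1)], [_ident(2)]))
    net.add_reaction(Reaction("swap", [("A", 1)], [("M", 1)], [[[0, 2], [0, 1]]]))
    net.add_reaction(Reaction("out", [("M", 1)], [("OUT", 1)], [_ident(2)]))
    net.substrate_label = {"S": [("10", 1.0)]}
    return net


@pytest.fixture(scope="session")
def yeast_network():
    from crabtree.network import build_central_carbon_network

    return build_central_carbon_network("crabtree_positive")


@pytest.fixture(scope="session")
def chemostat_truth(yeast_network):
    from crabtree.synth import reference_flux_scenario

    _, truth = reference_flux_scenario("positive_chemostat", yeast_network)
    return truth
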