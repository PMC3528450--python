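import numpy as np
import pytest

from crabtree.labeling import (EMUFragment, EMUSimulator,
                               MassIsotopomerDistribution, decompose_emu,
                               default_fragment_map, natural_abundance_convolve,
                               positional_enrichments, sfl_from_mid,
                               simulate_mids, simulate_sfl_dataset)
from crabtree.network import AtomMapNetwork, Metabolite, Reaction

from _oracles import enumerate_isotopomers, mid_from_isotopomers


class TestFragmentTypes:
    def test_positions_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            EMUFragment("A", (2, 1))

    def test_mid_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MassIsotopomerDistribution(EMUFragment("A", (1,)), np.array([0.5, 0.4]))


class TestDecomposition:
    def test_linear_chain_single_size3_system(self, linear_chain):
        dec = decompose_emu(linear_chain, [EMUFragment("C", (1, 2, 3))])
        assert [s.size for s in dec.systems] == [3]
        assert len(dec.systems[0].unknowns) == 3  # A, B, C full fragments

    def test_condensation_becomes_convolution(self, condensation_net):
        dec = decompose_emu(condensation_net, [EMUFragment("D", (1, 2, 3, 4))])
        sizes = [s.size for s in dec.systems]
        assert sizes == [2, 4]
        # the size-4 target is produced from two size-2 source fragments
        d_sys = dec.systems[-1]
        terms = d_sys.terms[d_sys.index[EMUFragment("D", (1, 2, 3, 4))]]
        assert any(len(sources) == 2 for _, _, sources in terms)

    def test_substrate_fragment_is_input(self, linear_chain):
        dec = decompose_emu(linear_chain, [EMUFragment("S", (1, 2, 3))])
        assert dec.systems == []
        assert EMUFragment("S", (1, 2, 3)) in dec.inputs

    def test_unreachable_fragment_flagged_unlabeled(self):
        net = AtomMapNetwork("island")
        net.add_metabolite(Metabolite("X", 2))
        net.add_metabolite(Metabolite("OUT", 2, "external", balanced=False))
        net.add_reaction(Reaction("out", [("X", 1)], [("OUT", 1)],
                                  [[[0, 1], [0, 2]]]))
        dec = decompose_emu(net, [EMUFragment("X", (1, 2))])
        frag = EMUFragment("X", (1, 2))
        assert frag in dec.dangling
        assert np.allclose(dec.inputs[frag], [1, 0, 0])


class TestSimulation:
    def test_fully_labeled_single_carbon(self):
        net = AtomMapNetwork("one")
        net.add_metabolite(Metabolite("A", 1, "external", balanced=False))
        net.add_metabolite(Metabolite("B", 1))
        net.add_metabolite(Metabolite("OUT", 1, "external", balanced=False))
        net.add_reaction(Reaction("u", [("A", 1)], [("B", 1)], [[[0, 1]]]))
        net.add_reaction(Reaction("o", [("B", 1)], [("OUT", 1)], [[[0, 1]]]))
        net.substrate_label = {"A": [("1", 1.0)]}
        mids = simulate_mids(net, {"u": 1.0, "o": 1.0}, [EMUFragment("B", (1,))])
        assert np.allclose(mids[0].fractions, [0, 1])

    def test_condensation_binomial_mid(self, condensation_net):
        flux = {"u": 2.0, "cond": 1.0, "out": 1.0}
        mids = simulate_mids(condensation_net, flux, [EMUFragment("D", (1, 2, 3, 4))])
        assert np.allclose(mids[0].fractions, [0.25, 0.5, 0.25, 0, 0], atol=1e-12)

    def test_symmetric_intermediate_splits_label(self, symmetric_net):
        flux = {"u": 1.0, "fm": 1.0, "out": 1.0}
        enr = positional_enrichments(symmetric_net, flux, "M")
        assert np.allclose(enr, [0.5, 0, 0, 0.5], atol=1e-12)

    def test_zero_flux_pool_raises_named_error(self, linear_chain):
        with pytest.raises(ValueError, match="zero inflow"):
            EMUSimulator(linear_chain, [EMUFragment("C", (1, 2, 3))],
                         check_steady_state=False).mids(
                {"u": 0.0, "r1": 0.0, "r2": 1.0, "out": 1.0})

    def test_steady_state_precondition_enforced(self, linear_chain):
        with pytest.raises(ValueError, match="steady state"):
            simulate_mids(linear_chain, {"u": 1.0, "r1": 0.5, "r2": 0.5, "out": 0.5},
                          [EMUFragment("C", (1, 2, 3))])

    def test_scale_invariance(self, yeast_network, chemostat_truth):
        fm = default_fragment_map()
        sim = EMUSimulator(yeast_network, fm.all_precursors())
        a = simulate_sfl_dataset(yeast_network, chemostat_truth, fm, simulator=sim)
        scaled = chemostat_truth.scaled(0.37)
        b = simulate_sfl_dataset(yeast_network, scaled, fm, simulator=sim)
        assert np.allclose(a["sfl_percent"], b["sfl_percent"], atol=1e-9)

    def test_mids_are_distributions(self, yeast_network, chemostat_truth):
        fm = default_fragment_map()
        sim = EMUSimulator(yeast_network, fm.all_precursors())
        mids = sim.mids(chemostat_truth)
        for frag, mid in mids.items():
            assert abs(mid.sum() - 1.0) < 1e-9
            assert (mid >= -1e-12).all()


class TestSFL:
    @pytest.mark.parametrize("fractions,expected", [
        ([1, 0], 0.0),
        ([0, 0, 1], 200.0),
        ([0.25, 0.5, 0.25], 100.0),
    ])
    def test_closed_form(self, fractions, expected):
        assert sfl_from_mid(np.array(fractions)) == pytest.approx(expected)

    def test_unlabeled_substrate_gives_zero_sfl(self, yeast_network, chemostat_truth):
        import copy

        net = copy.deepcopy(yeast_network)
        net.substrate_label = {"GLC": [("000000", 1.0)]}
        df = simulate_sfl_dataset(net, chemostat_truth)
        assert np.allclose(df["sfl_percent"], 0.0, atol=1e-12)

    def test_hand_solvable_branch_network(self, branch_net):
        # keep fraction f: enrichment of M C1 = f, of M C2 = 1 - f
        flux = {"u": 1.0, "keep": 0.7, "swap": 0.3, "out": 1.0}
        enr = positional_enrichments(branch_net, flux, "M")
        assert np.allclose(enr, [0.7, 0.3], atol=1e-12)


class TestOracleEquivalence:
    """EMU vs exhaustive positional-isotopomer enumeration."""

    def _compare(self, net, flux, targets, tol=1e-9):
        sim = EMUSimulator(net, targets, check_steady_state=False)
        mids = sim.mids(flux)
        dist = enumerate_isotopomers(net, flux)
        for frag in targets:
            oracle = mid_from_isotopomers(net, dist, frag)
            assert np.abs(oracle - mids[frag]).max() < tol

    def test_linear_chain(self, linear_chain):
        self._compare(linear_chain, {"u": 1, "r1": 1, "r2": 1, "out": 1},
                      [EMUFragment("C", (1, 2, 3)), EMUFragment("B", (1, 3))])

    def test_condensation(self, condensation_net):
        self._compare(condensation_net, {"u": 2, "cond": 1, "out": 1},
                      [EMUFragment("D", (1, 2, 3, 4)), EMUFragment("D", (2, 4))])

    def test_symmetric(self, symmetric_net):
        self._compare(symmetric_net, {"u": 1, "fm": 1, "out": 1},
                      [EMUFragment("M", (1, 2, 3, 4)), EMUFragment("F", (1, 4))])

    def test_branch(self, branch_net):
        self._compare(branch_net, {"u": 1, "keep": 0.42, "swap": 0.58, "out": 1},
                      [EMUFragment("M", (1, 2)), EMUFragment("M", (2,))])

    def test_full_yeast_network(self, yeast_network, chemostat_truth):
        """The built network agrees with enumeration too (stronger check)."""
        fm = default_fragment_map()
        sim = EMUSimulator(yeast_network, fm.all_precursors())
        mids = sim.mids(chemostat_truth)
        dist = enumerate_isotopomers(yeast_network, chemostat_truth)
        for frag, mid in mids.items():
            oracle = mid_from_isotopomers(yeast_network, dist, frag)
            assert np.abs(oracle - mid).max() < 1e-9


class TestLabelBalance:
    def test_total_label_conserved_linear_chain(self, linear_chain):
        """Label inflow (uptake x enrichment x carbons) equals outflow."""
        flux = {"u": 2.0, "r1": 2.0, "r2": 2.0, "out": 2.0}
        mids = simulate_mids(linear_chain, flux, [EMUFragment("C", (1, 2, 3))])
        sfl_out = sfl_from_mid(mids[0]) / 100.0   # labeled carbons per molecule
        # substrate has exactly 1 labeled carbon per molecule
        assert sfl_out * flux["out"] == pytest.approx(1.0 * flux["u"], abs=1e-9)


class TestExchangeFluxes:
    def test_exchange_mixes_label_upstream(self, linear_chain):
        """Bidirectional exchange cannot change a linear chain's output but
        is accepted and keeps MIDs valid distributions."""
        import copy

        net = copy.deepcopy(linear_chain)
        net.reactions["r1"] = Reaction("r1", [("A", 1)], [("B", 1)],
                                       [[[0, 1], [0, 2], [0, 3]]],
                                       reversible=True, exchange_allowed=True)
        flux = {"u": 1.0, "r1": 1.0, "r2": 1.0, "out": 1.0}
        sim = EMUSimulator(net, [EMUFragment("C", (1, 2, 3))])
        base = sim.mids(flux)[EMUFragment("C", (1, 2, 3))]
        with_x = sim.mids(flux, exchange={"r1": 0.5})[EMUFragment("C", (1, 2, 3))]
        assert np.allclose(base, with_x, atol=1e-9)
        assert abs(with_x.sum() - 1) < 1e-9


class TestNaturalAbundance:
    def test_round_trip(self):
        mid = np.array([0.2, 0.5, 0.3])
        conv = natural_abundance_convolve(mid, 2)
        back = natural_abundance_convolve(conv, 2, inverse=True)
        assert np.allclose(back, mid, atol=1e-12)
        assert conv[0] < mid[0]  # natural abundance shifts mass upward
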