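import numpy as np
import pandas as pd
import pytest

from crabtree.fluxfit import (FitConfig, FluxState, MeasurementSet,
                              FreeFluxBasis, fit_fluxes, linearized_flux_sd,
                              monte_carlo_intervals, normalize_fluxes,
                              steady_state_flux_map)
from crabtree.labeling import AminoAcidFragmentMap, EMUFragment
from crabtree.network import stoichiometric_matrix
from crabtree.synth import make_sfl_dataset, reference_flux_scenario


def branch_measurements(sfl_value: float, sd: float = 0.5) -> MeasurementSet:
    sfl = pd.DataFrame({"fragment_id": ["M1"], "sfl_percent": [sfl_value],
                        "sd_percent": [sd]})
    rates = pd.DataFrame({"reaction": ["out"], "rate": [100.0], "sd": [0.5]})
    return MeasurementSet(sfl, rates)


BRANCH_MAP = AminoAcidFragmentMap([("M1", [EMUFragment("M", (1,))]),
                                   ("M12", [EMUFragment("M", (1, 2))])])


class TestNormalize:
    def test_identity_when_basis_is_100(self):
        fs = FluxState({"HXK": 100.0, "X": 42.0})
        out = normalize_fluxes(fs, "HXK")
        assert out.net == fs.net

    def test_scale_round_trip(self):
        fs = FluxState({"HXK": 100.0, "X": 42.0})
        out = normalize_fluxes(fs.scaled(0.37), "HXK")
        assert out.net["X"] == pytest.approx(42.0, abs=1e-12)

    def test_idempotent(self):
        fs = FluxState({"HXK": 57.0, "X": 13.0})
        once = normalize_fluxes(fs, "HXK")
        twice = normalize_fluxes(once, "HXK")
        assert once.net == twice.net

    def test_zero_basis_rejected(self):
        with pytest.raises(ValueError, match="zero flux"):
            normalize_fluxes(FluxState({"HXK": 0.0}), "HXK")


class TestSteadyStateFluxMap:
    def test_targets_hit_exactly(self, yeast_network, chemostat_truth):
        assert chemostat_truth.net["PDH"] == pytest.approx(61.7, abs=1e-9)
        assert chemostat_truth.net["HXK"] == pytest.approx(100.0, abs=1e-9)

    def test_infeasible_targets_rejected(self, yeast_network):
        targets = {"HXK": 100.0, "ZWF": 40.0, "ADH": 0.0, "EX_GLYC": 0.0,
                   "EX_AC": 0.0, "EX_PYR": 0.0, "MAE": 4.0, "ICL": 2.0,
                   "PDH": 250.0}
        targets.update({f"BM_{p}": w * 7.0 for p, w in yeast_network.biomass_drains})
        with pytest.raises(ValueError, match="feasible"):
            steady_state_flux_map(yeast_network, targets)


class TestTwoBranchFit:
    """Substrate splits into two sinks with distinct label signatures: the
    fitted branch ratio must match the closed-form value implied by the
    observed SFL (enrichment of M carbon 1 = keep fraction)."""

    def test_branch_ratio_closed_form(self, branch_net):
        meas = branch_measurements(70.0)
        cfg = FitConfig(multistart=3, seed=1, basis_reaction="u",
                        fragment_map=BRANCH_MAP)
        fit = fit_fluxes(branch_net, meas, cfg)
        assert fit.converged
        ratio = fit.fluxes.net["keep"] / (fit.fluxes.net["keep"] + fit.fluxes.net["swap"])
        assert ratio == pytest.approx(0.70, abs=1e-3)

    def test_deterministic_given_seed(self, branch_net):
        meas = branch_measurements(35.0)
        cfg = FitConfig(multistart=3, seed=7, basis_reaction="u",
                        fragment_map=BRANCH_MAP)
        a = fit_fluxes(branch_net, meas, cfg)
        b = fit_fluxes(branch_net, meas, cfg)
        assert a.fluxes.net == b.fluxes.net


@pytest.fixture(scope="module")
def batch_fit(yeast_network):
    net, truth = reference_flux_scenario("positive_batch", yeast_network)
    meas = make_sfl_dataset(net, truth, noise_sd=0.0)
    fit = fit_fluxes(net, meas, FitConfig(multistart=4, seed=3))
    return truth, meas, fit


class TestYeastRecovery:
    def test_noise_free_parameter_recovery(self, yeast_network, batch_fit):
        truth, _, fit = batch_fit
        assert fit.converged
        for rid, planted in truth.net.items():
            assert fit.fluxes.net[rid] == pytest.approx(planted, abs=0.5), rid

    def test_fitted_fluxes_satisfy_steady_state_and_bounds(self, yeast_network, batch_fit):
        _, _, fit = batch_fit
        S = stoichiometric_matrix(yeast_network)
        v = np.array([fit.fluxes.net[r] for r in S.columns])
        assert np.abs(S.to_numpy() @ v).max() < 1e-9
        for rid, rxn in yeast_network.reactions.items():
            if not rxn.reversible:
                assert fit.fluxes.net[rid] >= 0

    def test_no_better_than_truth_artifact(self, yeast_network, batch_fit):
        """On noise-free data the optimum cannot beat the planted truth by
        more than numerical tolerance."""
        from crabtree.fluxfit import _residual_builder

        truth, meas, fit = batch_fit
        basis = FreeFluxBasis(yeast_network)
        cfg = FitConfig()
        residuals, _, fixed_j, _, _ = _residual_builder(yeast_network, meas, cfg, basis)
        u_truth = np.delete(basis.free_values(truth.net), fixed_j)
        ssr_truth = float((residuals(u_truth) ** 2).sum())
        assert fit.ssr <= ssr_truth + 1e-6


class TestMonteCarlo:
    def _fit(self, branch_net, sd=0.5, seed=1):
        meas = branch_measurements(70.0, sd=sd)
        cfg = FitConfig(multistart=2, seed=seed, basis_reaction="u",
                        fragment_map=BRANCH_MAP)
        return meas, cfg, fit_fluxes(branch_net, meas, cfg)

    def test_small_sd_gives_narrow_interval(self, branch_net):
        meas, cfg, fit = self._fit(branch_net, sd=0.01)
        mc = monte_carlo_intervals(branch_net, meas, fit, n_resamples=20,
                                   seed=2, config=cfg)
        row = mc.set_index("reaction").loc["keep"]
        assert row["hi97.5"] - row["lo2.5"] < 0.5
        assert row["lo2.5"] <= 70.0 <= row["hi97.5"]

    def test_widths_weakly_increase_with_sd(self, branch_net):
        widths = {}
        for sd in (0.5, 1.0):
            meas, cfg, fit = self._fit(branch_net, sd=sd)
            mc = monte_carlo_intervals(branch_net, meas, fit, n_resamples=50,
                                       seed=2, config=cfg).set_index("reaction")
            widths[sd] = mc.loc["keep", "hi97.5"] - mc.loc["keep", "lo2.5"]
        assert widths[1.0] > widths[0.5]

    def test_interval_coverage_of_planted_truth(self, branch_net):
        """Planted flux inside the 95% interval in >= 90% of synthetic runs."""
        rng = np.random.default_rng(11)
        hits = 0
        n_runs = 50
        for _ in range(n_runs):
            obs = 70.0 + rng.normal(0, 2.0)
            meas = branch_measurements(obs, sd=2.0)
            cfg = FitConfig(multistart=2, seed=1, basis_reaction="u",
                            fragment_map=BRANCH_MAP)
            fit = fit_fluxes(branch_net, meas, cfg)
            mc = monte_carlo_intervals(branch_net, meas, fit, n_resamples=30,
                                       seed=3, config=cfg).set_index("reaction")
            if mc.loc["keep", "lo2.5"] - 1e-9 <= 70.0 <= mc.loc["keep", "hi97.5"] + 1e-9:
                hits += 1
        assert hits >= int(0.9 * n_runs)

    def test_rejects_too_few_resamples(self, branch_net):
        meas, cfg, fit = self._fit(branch_net)
        with pytest.raises(ValueError, match="n_resamples"):
            monte_carlo_intervals(branch_net, meas, fit, n_resamples=5, config=cfg)


class TestMeasurementSet:
    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            MeasurementSet(pd.DataFrame(columns=["fragment_id", "sfl_percent",
                                                 "sd_percent"]),
                           pd.DataFrame(columns=["reaction", "rate", "sd"]))

    def test_nonpositive_sd_rejected(self):
        sfl = pd.DataFrame({"fragment_id": ["Ala"], "sfl_percent": [30.0],
                            "sd_percent": [0.0]})
        with pytest.raises(ValueError, match="sds"):
            MeasurementSet(sfl, pd.DataFrame(columns=["reaction", "rate", "sd"]))
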