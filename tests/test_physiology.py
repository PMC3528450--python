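import numpy as np
import pandas as pd
import pytest

from crabtree.physiology import (FermentationProfile, GLUCOSE_MG_PER_CMMOL,
                                 carbon_balance, compute_specific_uptake,
                                 compute_yields, fit_growth_rate, gas_rates,
                                 physio_summary, steady_state_windows)
from crabtree.synth import make_batch_profile, make_chemostat_profile


class TestGrowthRate:
    @pytest.mark.parametrize("mu", [0.47, 0.40])
    def test_noise_free_exponential_recovered_exactly(self, mu):
        prof = make_batch_profile(mu=mu, X0=0.05, n_points=12)
        fit = fit_growth_rate(prof)
        assert fit.mu == pytest.approx(mu, rel=1e-6)
        assert fit.r_squared > 0.999

    def test_constant_biomass_gives_zero_with_warning(self):
        df = pd.DataFrame({"time": np.linspace(0, 5, 6),
                           "biomass": np.full(6, 2.0),
                           "glucose": np.full(6, 10.0)})
        fit = fit_growth_rate(FermentationProfile("batch", df))
        assert fit.mu == 0.0
        assert fit.warning is not None

    def test_noisy_recovery_within_5_percent(self):
        prof = make_batch_profile(mu=0.40, n_points=20, noise_cv=0.02, seed=4)
        fit = fit_growth_rate(prof)
        assert fit.mu == pytest.approx(0.40, rel=0.05)

    def test_too_few_points_rejected(self):
        df = pd.DataFrame({"time": [0.0, 1.0], "biomass": [0.1, 0.2],
                           "glucose": [10.0, 9.0]})
        with pytest.raises(ValueError, match="3 points"):
            fit_growth_rate(FermentationProfile("batch", df))

    def test_explicit_window_respected(self):
        prof = make_batch_profile(mu=0.30, n_points=10)
        fit = fit_growth_rate(prof, window=(prof.data["time"].iloc[2],
                                            prof.data["time"].iloc[7]))
        assert fit.mu == pytest.approx(0.30, rel=1e-9)


class TestSpecificUptake:
    def test_chemostat_hand_value(self):
        # D=0.1, S_in=10, S=0, X=5.5 -> 0.1818 g/gDW/h = 6.056 C-mmol/gDW/h
        prof = make_chemostat_profile(D=0.1, S_in=10.0, yields={"Ysx": 0.55})
        q = compute_specific_uptake(prof)
        assert q == pytest.approx(0.1 * 10.0 / 5.5 * 1000 / GLUCOSE_MG_PER_CMMOL,
                                  rel=1e-9)
        assert q == pytest.approx(6.056, abs=2e-3)

    def test_batch_planted_qs_recovered(self):
        # plant q_s = 26.7 C-mmol/gDW/h via Ysx = mu / (q_s * 0.030026)
        mu, q_target = 0.47, 26.7
        ysx = mu / (q_target * GLUCOSE_MG_PER_CMMOL / 1000.0)
        prof = make_batch_profile(mu=mu, yields={"Ysx": ysx})
        q = compute_specific_uptake(prof)
        assert q == pytest.approx(q_target, rel=1e-3)

    def test_no_consumption_gives_zero(self):
        df = pd.DataFrame({"time": np.linspace(0, 3, 5),
                           "biomass": 0.1 * np.exp(0.3 * np.linspace(0, 3, 5)),
                           "glucose": np.full(5, 10.0)})
        prof = FermentationProfile("batch", df)
        assert compute_specific_uptake(prof) == 0.0


class TestYields:
    def test_chemostat_planted_ysx_exact(self):
        prof = make_chemostat_profile(D=0.1, S_in=10.0, yields={"Ysx": 0.55})
        assert compute_yields(prof)["Ysx"] == pytest.approx(0.55, abs=1e-12)

    def test_batch_planted_ethanol_yield(self):
        prof = make_batch_profile(mu=0.40, yields={"Ysx": 0.17, "YsEtOH": 0.33})
        y = compute_yields(prof)
        assert y["YsEtOH"] == pytest.approx(0.33, abs=1e-9)
        assert y["Ysx"] == pytest.approx(0.17, abs=1e-9)

    def test_zero_product_yield(self):
        prof = make_batch_profile(mu=0.40, yields={"Ysx": 0.5, "YsEtOH": 0.0})
        assert compute_yields(prof)["YsEtOH"] == 0.0


class TestGasRates:
    def test_constructed_otr_round_trips(self):
        from crabtree.synth import _offgas_for

        X = np.full(5, 2.0)
        q_o2 = np.full(5, 5.0)   # OTR = 10 mmol/L/h
        q_co2 = np.full(5, 5.0)
        df = pd.DataFrame({"time": np.arange(5.0), "biomass": X,
                           "glucose": np.full(5, 5.0)})
        df = pd.concat([df, _offgas_for(q_o2, q_co2, X)], axis=1)
        gas = gas_rates(FermentationProfile("batch", df))
        assert np.allclose(gas["otr"], 10.0, atol=1e-9)
        assert np.allclose(gas["ctr"], 10.0, atol=1e-9)
        assert np.allclose(gas["rq"], 1.0, atol=1e-12)

    def test_no_composition_change_gives_zero_and_flag(self):
        df = pd.DataFrame({"time": np.arange(4.0),
                           "biomass": 0.1 * np.exp(0.3 * np.arange(4.0)),
                           "glucose": np.linspace(10, 8, 4),
                           "y_o2_in": 0.2095, "y_co2_in": 0.0004,
                           "y_o2_out": 0.2095, "y_co2_out": 0.0004,
                           "gas_flow": 60.0, "volume": 1.0})
        prof = FermentationProfile("batch", df)
        gas = gas_rates(prof)
        assert np.allclose(gas["otr"], 0) and np.allclose(gas["ctr"], 0)
        summ = physio_summary(prof)
        assert summ.rq is None
        assert any("RQ undefined" in f for f in summ.flags)

    def test_degenerate_outlet_rejected(self):
        df = pd.DataFrame({"time": np.arange(3.0), "biomass": np.full(3, 1.0),
                           "glucose": np.full(3, 5.0),
                           "y_o2_in": 0.2, "y_co2_in": 0.0,
                           "y_o2_out": 0.6, "y_co2_out": 0.4,
                           "gas_flow": 60.0, "volume": 1.0})
        with pytest.raises(ValueError, match="degenerate"):
            gas_rates(FermentationProfile("batch", df))


class TestCarbonBalance:
    def test_respiratory_profile_closes_exactly(self):
        prof = make_batch_profile(mu=0.47, yields={"Ysx": 0.55})
        summ = physio_summary(prof)
        assert summ.carbon_recovery == pytest.approx(1.0, abs=1e-6)

    def test_fermentative_profile_closes(self):
        prof = make_batch_profile(mu=0.40, yields={"Ysx": 0.17, "YsEtOH": 0.33,
                                                   "YsGly": 0.04, "YsAc": 0.01})
        summ = physio_summary(prof)
        assert summ.carbon_recovery == pytest.approx(1.0, abs=1e-6)

    def test_deleted_product_carbon_shows_deficit(self):
        prof = make_batch_profile(mu=0.40, yields={"Ysx": 0.17, "YsEtOH": 0.33})
        summ = physio_summary(prof)
        # remove 10% of the product carbon terms from the summary
        summ.yields["YsEtOH"] *= 0.9
        summ.ctr_specific *= 0.9
        summ.otr_specific *= 0.9
        bio_frac = summ.mu_max * 1000.0 / 24.63 / summ.q_s_cmmol
        recovery, _ = carbon_balance(prof, summ)
        expected = bio_frac + 0.9 * (1.0 - bio_frac)
        assert recovery == pytest.approx(expected, abs=1e-6)


class TestRespiratoryQuotient:
    def test_fully_respiratory_rq_near_one(self):
        """With the CH1.8O0.5N0.2 biomass formula and RQ planted from the
        carbon balance, computed RQ stays in the consistency band."""
        prof = make_batch_profile(mu=0.47, yields={"Ysx": 0.55}, rq=1.05)
        summ = physio_summary(prof)
        assert 0.95 <= summ.rq <= 1.15


class TestChemostatIdentities:
    def test_mu_equals_d_and_yield_rate_identity(self):
        prof = make_chemostat_profile(D=0.1, S_in=10.0, yields={"Ysx": 0.55})
        summ = physio_summary(prof)
        assert summ.mu_max == pytest.approx(0.1, abs=1e-12)
        assert summ.yields["Ysx"] * summ.q_s_mass == pytest.approx(0.1, abs=1e-9)

    def test_steady_state_flag(self):
        prof = make_chemostat_profile(D=0.1, S_in=10.0)
        assert steady_state_windows(prof)
        short = FermentationProfile("chemostat", prof.data.iloc[:3].copy(),
                                    D=0.1, S_in=10.0)
        assert not steady_state_windows(short)


class TestProfileIO:
    def test_csv_round_trip(self, tmp_path):
        prof = make_chemostat_profile(D=0.1, S_in=10.0)
        path = tmp_path / "prof.csv"
        prof.to_csv(path)
        back = FermentationProfile.from_csv(path)
        assert back.mode == "chemostat"
        assert back.D == 0.1 and back.S_in == 10.0
        pd.testing.assert_frame_equal(back.data, prof.data, atol=1e-12)

    def test_invalid_time_rejected(self):
        df = pd.DataFrame({"time": [0.0, 0.0, 1.0], "biomass": [1, 1, 1],
                           "glucose": [5, 5, 5]})
        with pytest.raises(ValueError, match="strictly increasing"):
            FermentationProfile("batch", df)
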