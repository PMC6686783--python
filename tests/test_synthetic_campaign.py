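"""Generator structure: diel cycles, exact truth identities, noise model."""

import numpy as np
import pandas as pd
import pytest

from cospart.forward_models import AmbientMoleFractions, fcos_forward
from cospart.soil_cos import ChamberMeasurement, chamber_flux, fit_soil_model, molar_flow_from_volumetric
from cospart.synthetic_campaign import (
    DAYTIME_PAR_THRESHOLD,
    preset,
    simulate_chamber_campaign,
    simulate_meteo,
    simulate_observations,
    simulate_truth,
)


class TestMeteo:
    def test_par_noon_peak_and_midnight_zero(self, gra_truth):
        scen, truth = gra_truth
        noon = truth[(truth.index.hour == 12) & (truth.index.minute == 0)]
        assert np.allclose(noon["par"], scen.par_max)
        midnight = truth[(truth.index.hour == 0) & (truth.index.minute == 0)]
        assert np.allclose(midnight["par"], 0.0)

    def test_daily_par_integral_matches_half_sine(self, gra_truth):
        """Daily integral of the half-sine equals (2/pi)*par_max*daylength."""
        scen, truth = gra_truth
        one_day = truth.iloc[:48]["par"]
        integral = one_day.sum() * 1800.0  # umol m-2 per day
        expected = (2 / np.pi) * scen.par_max * scen.daylength_h * 3600.0
        assert integral == pytest.approx(expected, rel=0.01)

    def test_bit_reproducible_per_seed(self):
        m1 = simulate_meteo(preset("SAV", seed=5, n_days=2))
        m2 = simulate_meteo(preset("SAV", seed=5, n_days=2))
        assert m1.equals(m2)


class TestTruth:
    def test_night_truth(self, gra_truth):
        _, truth = gra_truth
        night = truth[truth["par"] <= DAYTIME_PAR_THRESHOLD]
        assert np.allclose(night["gpp_true"], 0.0)
        assert np.allclose(night["nee_true"], night["reco_true"])
        assert night["lru_true"].isna().all()
        # nocturnal residual canopy COS uptake from incomplete stomatal closure
        assert (night["f_cos_canopy_true"] < 0).all()

    def test_daytime_cos_consistency(self, gra_truth):
        """Canopy COS truth reproduces the forward model exactly."""
        _, truth = gra_truth
        day = truth[truth["par"] > DAYTIME_PAR_THRESHOLD]
        amb = AmbientMoleFractions(day["chi_co2"].to_numpy(), day["chi_cos"].to_numpy())
        expect = -fcos_forward(day["gpp_true"].to_numpy(), day["lru_true"].to_numpy(), amb)
        assert np.allclose(day["f_cos_canopy_true"].to_numpy(), expect, rtol=0, atol=0)

    def test_sav_soil_sign_pattern(self):
        """Savanna preset: daytime soil emission, nighttime soil uptake."""
        scen = preset("SAV", seed=3, n_days=5)
        truth = simulate_truth(scen, simulate_meteo(scen))
        day = truth["par"] > DAYTIME_PAR_THRESHOLD
        assert truth.loc[day, "f_soil_true"].median() > 0
        assert truth.loc[~day, "f_soil_true"].median() < 0

    def test_nee_positive_at_night_cos_uptake_continues(self):
        """Diel composite shape: night NEE is a source, night COS a weak sink."""
        for name in ("GRA", "DBF"):
            scen = preset(name, seed=1, n_days=4)
            truth = simulate_truth(scen, simulate_meteo(scen))
            night = truth[truth["par"] <= DAYTIME_PAR_THRESHOLD]
            day = truth[truth["par"] > DAYTIME_PAR_THRESHOLD]
            assert (night["nee_true"] > 0).all()
            night_uptake = -night["f_cos_canopy_true"].mean()
            peak_uptake = -day["f_cos_canopy_true"].min()
            assert 0 < night_uptake < peak_uptake


class TestObservations:
    def test_zero_noise_returns_truth(self, gra_truth):
        _, truth = gra_truth
        obs = simulate_observations(truth, (0.0, 0.0), seed=9)
        assert np.allclose(obs["nee"], truth["nee_true"])
        assert np.allclose(obs["fcos_eco"], truth["f_cos_canopy_true"] + truth["f_soil_true"])

    def test_noise_sd_matches_sigma(self):
        scen = preset("GRA", seed=2, n_days=210)  # ~10^4 records
        truth = simulate_truth(scen, simulate_meteo(scen))
        obs = simulate_observations(truth, (1.0, 3.0), seed=8)
        assert np.std(obs["nee"] - truth["nee_true"]) == pytest.approx(1.0, rel=0.03)
        assert np.std(obs["fcos_eco"] - truth["f_cos_eco_true"]) == pytest.approx(3.0, rel=0.03)

    def test_seeds_change_noise_not_truth(self, gra_truth):
        _, truth = gra_truth
        o1 = simulate_observations(truth, (1.0, 3.0), seed=1)
        o2 = simulate_observations(truth, (1.0, 3.0), seed=2)
        assert not np.allclose(o1["nee"], o2["nee"])
        assert np.allclose(o1["nee_true"], o2["nee_true"])

    def test_negative_sigma_rejected(self, gra_truth):
        _, truth = gra_truth
        with pytest.raises(ValueError):
            simulate_observations(truth, (-1.0, 3.0), seed=1)


class TestChamberCampaign:
    def test_zero_noise_round_trip_exact(self):
        scen = preset("GRA", seed=4, n_days=2)
        ch = simulate_chamber_campaign(scen, n_chambers=1, noise_ppt=0.0)
        fluxes = []
        for _, row in ch.iterrows():
            q = molar_flow_from_volumetric(row["q_lpm"], row["temp_c"], row["press_hpa"])
            fluxes.append(
                chamber_flux(ChamberMeasurement(q, row["c_ambient_ppt"], row["c_chamber_ppt"], row["area_m2"]))
            )
        assert np.allclose(fluxes, ch["f_soil_true"], rtol=1e-10)

    def test_noisy_chambers_recover_radiative_slope_sign(self):
        """Fitting the soil model on noisy chamber obs recovers daytime emission."""
        scen = preset("SAV", seed=6, n_days=10)
        ch = simulate_chamber_campaign(scen, n_chambers=3, noise_ppt=1.0)
        fluxes = []
        for _, row in ch.iterrows():
            q = molar_flow_from_volumetric(row["q_lpm"], row["temp_c"], row["press_hpa"])
            fluxes.append(
                chamber_flux(ChamberMeasurement(q, row["c_ambient_ppt"], row["c_chamber_ppt"], row["area_m2"]))
            )
        model = fit_soil_model(ch[["sw_soil", "t_soil", "swc"]], fluxes, seed=0)
        drivers_hi = ch[ch["sw_soil"] > ch["sw_soil"].quantile(0.8)][["sw_soil", "t_soil", "swc"]]
        drivers_lo = ch[ch["sw_soil"] == 0][["sw_soil", "t_soil", "swc"]]
        from cospart.soil_cos import predict_soil_flux

        assert predict_soil_flux(model, drivers_hi).mean() > predict_soil_flux(model, drivers_lo).mean()

    def test_times_outside_campaign_rejected(self):
        scen = preset("GRA", seed=4, n_days=2)
        bad = pd.DatetimeIndex(["2030-01-01 00:00"])
        with pytest.raises(ValueError, match="outside"):
            simulate_chamber_campaign(scen, times=bad)
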