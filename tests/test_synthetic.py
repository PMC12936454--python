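"""The generator reproduces its configured study conditions."""

import numpy as np
import pandas as pd
import pytest

import agrocycle as ac
from agrocycle.config import CO2_PPM, ClimateScenarioSpec


@pytest.fixture(scope="module")
def hist():
    return ac.scenario_by_name("historical")


@pytest.fixture(scope="module")
def plus4():
    return ac.scenario_by_name("+4C_MPI")


def _twin(scenario):
    """Unwarmed scenario on the same noise stream."""
    return ClimateScenarioSpec("historical", 0, CO2_PPM[0], scenario.esm_label)


class TestSites:
    def test_seeded_determinism(self):
        a = ac.generate_sites(1, seed=1)
        b = ac.generate_sites(1, seed=1)
        assert a == b

    def test_mean_topsoil_soc_near_regional_average(self):
        sites = ac.generate_sites(500, seed=7)
        mean = np.mean([s.soc0_topsoil for s in sites])
        assert mean == pytest.approx(78.0, rel=0.05)

    def test_profile_stock_exceeds_topsoil(self):
        for s in ac.generate_sites(50, seed=2):
            assert s.soc0_profile >= s.soc0_topsoil > 0

    def test_empty_request_rejected(self):
        with pytest.raises(ValueError):
            ac.generate_sites(0, seed=1)


class TestWeather:
    def test_historical_precipitation_targets_annual_mean(self, config, hist):
        totals = []
        for site in ac.generate_sites(8, seed=5, config=config):
            w = ac.generate_weather(site, hist, 30, seed=5, config=config)
            totals.append(w.groupby(w["date"].dt.year)["precip"].sum().mean())
        assert np.mean(totals) == pytest.approx(837.0, rel=0.05)

    def test_historical_temperature_targets_annual_mean(self, one_site, config, hist):
        w = ac.generate_weather(one_site, hist, 30, seed=5, config=config)
        tmean = ((w["tmin"] + w["tmax"]) / 2).mean()
        assert tmean == pytest.approx(11.0, abs=0.6)

    def test_warming_offset_is_exactly_additive(self, one_site, config, plus4):
        wf = ac.generate_weather(one_site, plus4, 5, seed=9, config=config)
        wh = ac.generate_weather(one_site, _twin(plus4), 5, seed=9, config=config)
        np.testing.assert_allclose(
            (wf["tmin"] - wh["tmin"]).to_numpy(), 4.0, atol=1e-12
        )
        np.testing.assert_allclose(
            (wf["tmax"] - wh["tmax"]).to_numpy(), 4.0, atol=1e-12
        )

    def test_summer_precipitation_strictly_lower_under_warming(
        self, one_site, config, plus4
    ):
        wf = ac.generate_weather(one_site, plus4, 10, seed=9, config=config)
        wh = ac.generate_weather(one_site, _twin(plus4), 10, seed=9, config=config)
        jja_f = wf.loc[wf["date"].dt.month.isin([6, 7, 8]), "precip"].sum()
        jja_h = wh.loc[wh["date"].dt.month.isin([6, 7, 8]), "precip"].sum()
        assert jja_f < jja_h

    def test_pet_increases_with_warming(self, one_site, config, plus4):
        wf = ac.generate_weather(one_site, plus4, 10, seed=9, config=config)
        wh = ac.generate_weather(one_site, _twin(plus4), 10, seed=9, config=config)
        assert wf["pet"].sum() > wh["pet"].sum()

    def test_physical_invariants(self, hist_weather):
        assert (hist_weather["tmax"] >= hist_weather["tmin"]).all()
        assert (hist_weather["precip"] >= 0).all()
        assert (hist_weather["pet"] >= 0).all()

    def test_weather_is_deterministic(self, one_site, config, hist):
        a = ac.generate_weather(one_site, hist, 3, seed=4, config=config)
        b = ac.generate_weather(one_site, hist, 3, seed=4, config=config)
        pd.testing.assert_frame_equal(a, b)


@pytest.fixture(scope="module")
def outcome(one_site, config, hist, hist_weather, plans):
    return {
        name: ac.generate_season_outcomes(
            one_site, hist, plan, hist_weather, seed=3, config=config
        )
        for name, plan in plans.items()
    }


class TestSeasonOutcomes:
    def test_one_season_per_year_and_24_soc_entries(self, outcome):
        for seasons, soc in outcome.values():
            assert list(seasons["year_index"]) == list(range(1, 25))
            assert len(soc) == 24
            assert soc[["dsoc_topsoil", "dsoc_profile"]].notna().all().all()

    def test_profile_change_never_below_topsoil_change(self, outcome):
        for _, soc in outcome.values():
            assert (soc["dsoc_profile"] >= soc["dsoc_topsoil"] - 1e-12).all()

    def test_fluxes_are_nonnegative(self, outcome):
        for seasons, _ in outcome.values():
            for col in ("yield_mg_ha", "n_fertilizer", "manure_n_applied",
                        "n2o_direct", "no3_leached"):
                assert (seasons[col] >= 0).all(), col

    def test_deterministic_for_fixed_seed(self, one_site, config, hist,
                                          hist_weather, plans):
        a, soc_a = ac.generate_season_outcomes(
            one_site, hist, plans["BAU"], hist_weather, seed=3, config=config
        )
        b, soc_b = ac.generate_season_outcomes(
            one_site, hist, plans["BAU"], hist_weather, seed=3, config=config
        )
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(soc_a, soc_b)

    def test_zero_noise_yields_exactly_base_times_multiplier(
        self, one_site, config, hist, hist_weather, plans
    ):
        cfg = ac.default_config()
        for c in cfg["crops"].values():
            c["cv"] = 0.0
        cfg["cover_biomass_cv"] = 0.0
        cfg["wet_coupling"]["k_wet"] = {r: 0.0 for r in cfg["wet_coupling"]["k_wet"]}
        cfg["wet_coupling"]["k_dry"] = 0.0
        seasons, _ = ac.generate_season_outcomes(
            one_site, hist, plans["Vegan"], hist_weather, seed=3, config=cfg
        )
        expected = seasons["crop"].map(
            {k: v["base_yield"] for k, v in cfg["crops"].items()}
        )
        np.testing.assert_allclose(
            seasons["yield_mg_ha"], expected * seasons["duration"]
        )

    def test_weather_length_mismatch_rejected(self, one_site, config, hist, plans):
        short = ac.generate_weather(one_site, hist, 10, seed=3, config=config)
        with pytest.raises(ValueError):
            ac.generate_season_outcomes(
                one_site, hist, plans["BAU"], short, seed=3, config=config
            )

    def test_icls_receives_its_own_manure(self, outcome):
        seasons, _ = outcome["ICLS"]
        assert seasons.loc[seasons["position"] == 1, "manure_n_applied"].min() > 0

    def test_leaching_baseline_recovered_across_sites(self, config, hist, plans):
        means = []
        for site in ac.generate_sites(60, seed=13, config=config):
            w = ac.generate_weather(site, hist, 24, seed=13, config=config)
            for plan in plans.values():
                seasons, _ = ac.generate_season_outcomes(
                    site, hist, plan, w, seed=13, config=config
                )
                means.append(seasons["no3_leached"].mean())
        assert np.mean(means) == pytest.approx(4.5, abs=0.7)

    def test_wet_extremes_depress_wheat_yields(self, config, hist, plans):
        devs = {"wet": [], "mid": []}
        for site in ac.generate_sites(30, seed=21, config=config):
            w = ac.generate_weather(site, hist, 24, seed=21, config=config)
            seasons, _ = ac.generate_season_outcomes(
                site, hist, plans["BAU"], w, seed=21, config=config
            )
            ww = seasons[seasons["crop"] == "WW"]
            devs["wet"] += list(ww.loc[ww["mam_z"] > 1.0, "yield_mg_ha"])
            devs["mid"] += list(
                ww.loc[ww["mam_z"].abs() <= 0.5, "yield_mg_ha"]
            )
        assert np.mean(devs["wet"]) < np.mean(devs["mid"])
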