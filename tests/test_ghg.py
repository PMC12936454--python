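"""GHG budget terms reproduce the published emission arithmetic."""

import numpy as np
import pandas as pd
import pytest

import agrocycle as ac
from agrocycle.ghg import GwpSet, aggregate_ch4


class TestSoilCO2:
    def test_no_change_no_flux(self):
        assert ac.soil_co2(np.zeros(24)) == 0.0

    def test_sequestration_is_negative_emission(self):
        # +0.3 Mg C/ha/yr stored -> -1.10 Mg CO2/ha/yr
        assert ac.soil_co2(np.full(24, 0.3)) == pytest.approx(-1.10, abs=5e-3)

    def test_loss_is_positive_emission(self):
        assert ac.soil_co2(np.full(24, -0.23)) == pytest.approx(0.843, abs=5e-4)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            ac.soil_co2(np.zeros(23))


class TestIndirectN2O:
    def test_zero_inputs(self):
        assert ac.indirect_n2o(0, 0) == 0

    def test_leaching_fraction_is_three_quarters_percent(self):
        assert ac.indirect_n2o(100.0, 0.0) == pytest.approx(0.75)

    def test_fertilizer_fraction_is_one_tenth_percent(self):
        assert ac.indirect_n2o(0.0, 200.0) == pytest.approx(0.2)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            ac.indirect_n2o(-1.0, 0.0)


class TestManagementCO2:
    def test_no_operations(self):
        assert ac.management_co2({}) == 0.0

    def test_single_combine_pass(self):
        assert ac.management_co2({"combine": 1}) == pytest.approx(60.94, abs=0.01)

    def test_plough_plus_two_tillage_passes(self):
        got = ac.management_co2({"plough": 1, "surface_tillage": 2})
        assert got == pytest.approx(115.34, abs=0.01)

    def test_fuel_arithmetic_from_printed_factors(self):
        got = ac.management_co2({"combine": 2, "plough": 1, "surface_tillage": 3})
        fuel = 2 * 20.5 + 27.6 + 3 * 5.6
        assert got == pytest.approx(fuel * 0.81 * 3.67)


class TestFertilizerCO2:
    @pytest.mark.parametrize(
        "n,expected", [(0.0, 0.0), (1.0, 6.17), (160.0, 987.2)]
    )
    def test_embodied_emissions(self, n, expected):
        assert ac.fertilizer_co2(n) == pytest.approx(expected)


class TestGwpStar:
    def test_all_zero_series(self):
        assert np.allclose(ac.gwp_star_series(np.zeros(24)), 0.0)

    def test_constant_series_keeps_quarter_of_gwp100(self):
        gwp = GwpSet()
        e = np.full(24, 10.0)
        star = ac.gwp_star_series(e, gwp)
        np.testing.assert_allclose(star, 0.25 * gwp.gwp100_ch4 * 10.0)

    def test_single_pulse_counts_four_times_gwp100(self):
        gwp = GwpSet()
        e = np.zeros(30)
        e[25] = 5.0  # far enough in: the 20-yr look-back sees the true zero
        star = ac.gwp_star_series(e, gwp)
        assert star[25] == pytest.approx(4.0 * gwp.gwp100_ch4 * 5.0)

    def test_declining_emissions_can_go_negative(self):
        e = np.concatenate([np.full(4, 10.0), np.full(20, 1.0)])
        assert ac.gwp_star_series(e).min() < 0

    def test_aggregate_stable_series_below_gwp100(self):
        gwp = GwpSet()
        e = np.full(24, 8.0)
        assert aggregate_ch4(e, gwp, "gwpstar") < aggregate_ch4(e, gwp, "gwp100")

    def test_nonpositive_gwp_rejected(self):
        with pytest.raises(ValueError):
            GwpSet(gwp100_ch4=-1.0)


def _frame(n=24, **overrides):
    base = {
        "year_index": np.arange(1, n + 1),
        "n_fertilizer": 0.0,
        "no3_leached": 0.0,
        "n2o_direct": 0.0,
        "n_combine": 0,
        "n_plough": 0,
        "n_surface_tillage": 0,
    }
    base.update(overrides)
    return pd.DataFrame(base)


def _soc(n=24, profile=0.0):
    return pd.DataFrame(
        {"year_index": np.arange(1, n + 1), "dsoc_topsoil": 0.0,
         "dsoc_profile": profile}
    )


class TestAssembleBudget:
    def test_all_zero_inputs_zero_budget(self, config):
        b = ac.assemble_budget(_frame(), _soc(), None, config=config)
        assert b.net == 0.0
        assert all(v == 0.0 for v in b.as_dict().values())

    def test_fertilizer_only_budget(self, config):
        b = ac.assemble_budget(
            _frame(n_fertilizer=100.0), _soc(), None, config=config
        )
        assert b.co2_fertilizer == pytest.approx(0.617)
        # plus the fertilizer share of indirect N2O: 0.1 kg N2O-N
        assert b.n2o_indirect == pytest.approx(
            0.1 * 44 / 28 * 273.0 / 1000.0
        )
        assert b.co2_soil == b.co2_management == b.n2o_direct == 0.0
        assert b.ch4_total == b.manure_n2o == 0.0

    def test_net_equals_sum_of_terms(self, small_tables):
        b = small_tables["budgets"]
        terms = b[
            ["co2_soil", "co2_fertilizer", "co2_management", "n2o_direct",
             "n2o_indirect", "ch4_total", "manure_n2o"]
        ].sum(axis=1)
        np.testing.assert_allclose(terms, b["net"], atol=1e-9)

    def test_only_soil_term_can_be_negative(self, small_tables):
        b = small_tables["budgets"]
        for col in ("co2_fertilizer", "co2_management", "n2o_direct",
                    "n2o_indirect", "manure_n2o"):
            assert (b[col] >= 0).all(), col

    def test_additivity_over_independent_sources(self, config):
        s1 = _frame(n_fertilizer=80.0, no3_leached=3.0, n2o_direct=1.0,
                    n_combine=1)
        s2 = _frame(n_fertilizer=40.0, no3_leached=1.5, n2o_direct=0.5,
                    n_plough=1)
        both = s1.copy()
        for col in ("n_fertilizer", "no3_leached", "n2o_direct", "n_combine",
                    "n_plough", "n_surface_tillage"):
            both[col] = s1[col] + s2[col]
        soc1, soc2 = _soc(profile=0.1), _soc(profile=-0.05)
        soc_both = _soc(profile=0.05)
        b1 = ac.assemble_budget(s1, soc1, None, config=config)
        b2 = ac.assemble_budget(s2, soc2, None, config=config)
        b = ac.assemble_budget(both, soc_both, None, config=config)
        for term, val in b.as_dict().items():
            assert val == pytest.approx(
                b1.as_dict()[term] + b2.as_dict()[term], abs=1e-9
            ), term

    def test_stable_methane_makes_gwpstar_net_smaller(self, config):
        lv = pd.DataFrame(
            {"year_index": np.arange(1, 25), "ch4_enteric": 30.0,
             "ch4_storage": 1.0, "ch4_spreading": 4.0, "n2o_storage": 0.2}
        )
        b100 = ac.assemble_budget(_frame(), _soc(), lv, metric="gwp100",
                                  config=config)
        bstar = ac.assemble_budget(_frame(), _soc(), lv, metric="gwpstar",
                                   config=config)
        assert bstar.net < b100.net
        assert bstar.ch4_total == pytest.approx(0.25 * b100.ch4_total)

    def test_metric_choice_does_not_change_scenario_ranking(self):
        """GWP100 vs GWP* changes magnitudes, not the scenario hierarchy."""
        nets = {}
        for metric in ("gwp100", "gwpstar"):
            cfg = ac.default_config()
            cfg["run"].update(
                n_sites=4, scenarios=["historical"], seed=11, metric=metric
            )
            b = ac.run_pipeline(cfg)["budgets"]
            order = b.groupby("rotation")["net"].mean().sort_values()
            nets[metric] = list(order.index)
        assert nets["gwp100"] == nets["gwpstar"]

    def test_mismatched_coverage_rejected(self, config):
        with pytest.raises(ValueError):
            ac.assemble_budget(_frame(24), _soc(23), None, config=config)
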