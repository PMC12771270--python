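import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from droughtsoc.climate import (
    ClimateMonth,
    WaterState,
    classify_zone,
    day_length_correction,
    partition_rs,
    run_water_balance,
    step_water,
    thornthwaite_pet,
)

from .conftest import constant_forcing


def _oracle_thornthwaite(temps12, corr):
    """Independent transcription of the 1948 formulation (single year)."""
    import math

    heat = sum((t / 5.0) ** 1.514 for t in temps12 if t > 0)
    a = 6.75e-7 * heat**3 - 7.71e-5 * heat**2 + 1.792e-2 * heat + 0.49239
    out = []
    for t, k in zip(temps12, corr):
        if t <= 0:
            out.append(0.0)
        elif t < 26.5:
            out.append(16.0 * (10.0 * t / heat) ** a * k)
        else:
            out.append((-415.85 + 32.24 * t - 0.43 * t * t) * k)
    return out


class TestThornthwaite:
    def test_cold_months_zero(self):
        temps = [-5.0, -2.0] + [10.0] * 10
        pet = thornthwaite_pet(temps, latitude=50.0)
        assert pet[0] == 0.0 and pet[1] == 0.0
        assert np.all(pet[2:] > 0)

    def test_all_frozen_year_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            pet = thornthwaite_pet([-1.0] * 12, latitude=50.0)
        assert np.all(pet == 0.0)

    def test_hot_branch_equator_matches_oracle(self):
        # constant 26.5 degC at the equator exercises the hot-temperature branch
        corr = day_length_correction(0.0)
        pet = thornthwaite_pet([26.5] * 12, latitude=0.0)
        np.testing.assert_allclose(pet, _oracle_thornthwaite([26.5] * 12, corr),
                                   rtol=1e-12)
        # January: (-415.85 + 32.24*26.5 - 0.43*26.5^2) * 31/30
        assert pet[0] == pytest.approx(136.5425 * 31 / 30, abs=1e-3)

    def test_mild_branch_matches_oracle(self):
        temps = [2.0, 3.0, 5.0, 8.0, 11.0, 14.0, 16.0, 15.0, 12.0, 9.0, 5.0, 3.0]
        corr = day_length_correction(53.0)
        np.testing.assert_allclose(
            thornthwaite_pet(temps, latitude=53.0),
            _oracle_thornthwaite(temps, corr),
            rtol=1e-12,
        )

    def test_linear_in_correction(self):
        temps = [10.0] * 12
        corr = day_length_correction(40.0)
        np.testing.assert_allclose(
            thornthwaite_pet(temps, correction=2 * corr),
            2 * thornthwaite_pet(temps, correction=corr),
        )

    @given(st.integers(min_value=0, max_value=11),
           st.floats(min_value=0.5, max_value=8.0))
    @settings(max_examples=40, derandomize=True)
    def test_monotone_in_temperature_all_else_equal(self, month, bump):
        # warming one month of a realistic series raises that month's PET
        base = [2.0, 3.0, 5.0, 8.0, 11.0, 14.0, 16.0, 15.0, 12.0, 9.0, 5.0, 3.0]
        warmer = list(base)
        warmer[month] += bump
        a = thornthwaite_pet(base, latitude=45.0)
        b = thornthwaite_pet(warmer, latitude=45.0)
        assert b[month] >= a[month]

    def test_input_validation(self):
        with pytest.raises(ValueError):
            thornthwaite_pet([5.0] * 10)
        with pytest.raises(ValueError):
            thornthwaite_pet([5.0] * 12, latitude=80.0)


class TestWaterBalance:
    def test_steady_state_p_equals_pet(self, site_layers):
        fc = np.array([la.water_capacity_fc for la in site_layers])
        state = WaterState(fc.copy())
        cm = ClimateMonth(0, 6, p=50.0, temp=10.0, pet=50.0)
        out = step_water(state, cm, site_layers)
        np.testing.assert_allclose(out.water, fc)
        assert out.wb["surplus"] == pytest.approx(0.0)
        assert out.wb["deficit"] == pytest.approx(0.0)

    def test_utilisation_and_deficit_accounting(self, site_layers):
        # profile holds 20 mm above the lower bound, demand is 30 mm
        wmin = np.array([la.water_min for la in site_layers])
        water = wmin + 20.0 * wmin / wmin.sum()
        out = step_water(
            WaterState(water), ClimateMonth(0, 7, 0.0, 15.0, 30.0), site_layers
        )
        assert out.wb["utilisation"] == pytest.approx(20.0)
        assert out.wb["deficit"] == pytest.approx(10.0)

    def test_drought_forcing_lowers_profile_water_every_window_month(
        self, site_layers
    ):
        base = constant_forcing(72, p=100.0, temp=9.0, pet=80.0)
        drought = base.copy()
        window = base["month"].between(3, 9)
        drought.loc[window, "P_mm"] *= 0.75
        wb_c, _ = run_water_balance(base, site_layers)
        wb_d, _ = run_water_balance(drought, site_layers)
        in_window = window.to_numpy()
        assert np.all(
            wb_d["profile_water_mm"].to_numpy()[in_window]
            < wb_c["profile_water_mm"].to_numpy()[in_window]
        )

    def test_mass_balance_closes(self, site_layers):
        rng = np.random.default_rng(7)
        forcing = constant_forcing(120, p=0.0, temp=9.0, pet=0.0)
        forcing["P_mm"] = rng.uniform(0, 250, 120)
        forcing["PET_mm"] = rng.uniform(0, 120, 120)
        wb, _ = run_water_balance(forcing, site_layers)
        assert np.abs(wb["closure"]).max() < 1e-9

    def test_zero_capacity_layers_pass_water_through(self, site_layers):
        from droughtsoc.profile import layer_capacities

        layers = layer_capacities(
            [la for la in site_layers], "prescribed", [0.0] * 6
        )
        out = step_water(
            WaterState(np.zeros(6)), ClimateMonth(0, 1, 80.0, 5.0, 10.0), layers
        )
        assert out.wb["surplus"] == pytest.approx(70.0)  # P minus ET-from-P
        assert out.profile_total == pytest.approx(0.0)


class TestZones:
    @pytest.mark.parametrize(
        "water,zone",
        [(70.0, "Dry"), (95.0, "Moderate"), (120.0, "Moist"),
         (80.0, "Moderate"), (110.0, "Moderate"), (110.0001, "Moist"),
         (79.999, "Dry"), (0.0, "Dry")],
    )
    def test_boundaries(self, water, zone):
        assert classify_zone(water) == zone

    @given(st.floats(min_value=0.0, max_value=500.0))
    @settings(max_examples=50, derandomize=True)
    def test_partition_of_nonnegative_reals(self, w):
        assert classify_zone(w) in {"Dry", "Moderate", "Moist"}

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_zone(-1.0)


class TestPartitionRs:
    @pytest.mark.parametrize(
        "month,rh", [(6, 46.0), (7, 46.0), (1, 59.0), (12, 59.0),
                     (4, 52.5), (10, 52.5)]
    )
    def test_seasonal_fractions(self, month, rh):
        got_rh, got_ra = partition_rs(100.0, month)
        assert got_rh == pytest.approx(rh)
        assert got_rh + got_ra == pytest.approx(100.0)

    def test_zero_rs(self):
        assert partition_rs(0.0, 6) == (0.0, 0.0)

    def test_month_out_of_range(self):
        with pytest.raises(ValueError):
            partition_rs(10.0, 13)
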