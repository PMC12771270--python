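import numpy as np
import pytest

from droughtsoc.model import (
    ModelParams,
    PoolState,
    SpinupError,
    partition_inputs,
    rate_modifier_temp,
    rate_modifier_water,
    run_simulation,
    spinup,
    step_month,
)
from droughtsoc.profile import co2_partition_fraction

from .conftest import constant_forcing


def single_layer_params(**kw):
    return ModelParams(depth_allocation=[1.0], **kw)


def optimum_forcing(n_months, layers, params):
    """Forcing that keeps every layer at field capacity with m_T = m_W = 1."""
    return constant_forcing(n_months, p=60.0, temp=params.t_ref, pet=60.0)


class TestPartitionInputs:
    def test_even_ratio(self):
        add = partition_inputs(100.0, single_layer_params(dpm_rpm_ratio=1.0))
        assert add[0, 0] == pytest.approx(50.0)
        assert add[0, 1] == pytest.approx(50.0)

    def test_resistant_litter_ratio(self):
        add = partition_inputs(100.0, single_layer_params(dpm_rpm_ratio=0.25))
        assert add[0, 0] == pytest.approx(20.0)
        assert add[0, 1] == pytest.approx(80.0)

    def test_zero_and_negative(self, params):
        assert partition_inputs(0.0, params).sum() == 0.0
        with pytest.raises(ValueError):
            partition_inputs(-1.0, params)

    def test_depth_allocation_applied(self, params):
        add = partition_inputs(1000.0, params)
        np.testing.assert_allclose(
            add.sum(axis=1), 1000.0 * np.array(params.depth_allocation)
        )


class TestRateModifiers:
    def test_temp_reference_is_one(self, params):
        assert rate_modifier_temp(params.t_ref, params) == pytest.approx(1.0)

    def test_temp_monotone(self, params):
        assert rate_modifier_temp(5.0, params) < rate_modifier_temp(15.0, params)

    def test_temp_against_direct_evaluation(self, params):
        import math

        f = lambda t: 47.91 / (1.0 + math.exp(106.06 / (t + 18.27)))
        assert rate_modifier_temp(9.3, params) == pytest.approx(
            f(9.3) / f(params.t_ref), rel=1e-12
        )

    def test_water_optimum_and_extremes(self, params):
        fc = 10.0
        assert rate_modifier_water(fc, fc, params) == pytest.approx(1.0)
        assert rate_modifier_water(1.4 * fc, fc, params) < 1.0
        # at the wilting bound (0.2 fc): exactly the dry floor
        assert rate_modifier_water(0.2 * fc, fc, params) == pytest.approx(
            params.dry_floor
        )
        # at saturation headroom: exactly the anoxic floor
        assert rate_modifier_water(params.headroom * fc, fc, params) == (
            pytest.approx(params.anoxic_floor)
        )

    def test_water_bounds(self, params):
        fc = 12.0
        w = np.linspace(0, 3 * fc, 200)
        m = rate_modifier_water(w, fc, params)
        assert np.all(m > 0) and np.all(m <= 1.0)


class TestStepMonth:
    def test_single_pool_exponential_decay(self, site_layers, params):
        # DPM-only stock, modifiers pinned at 1: 12 steps give C0 * exp(-k)
        stocks = np.zeros((6, 4))
        stocks[:, 0] = 100.0
        state = PoolState(stocks)
        fc = np.array([la.water_capacity_fc for la in site_layers])
        for m in range(12):
            state, _ = step_month(state, params.t_ref, fc, site_layers, params)
        expected = 100.0 * np.exp(-params.k["dpm"])
        np.testing.assert_allclose(state.pool("dpm"), expected, rtol=1e-9)

    def test_zero_rates_identity(self, site_layers):
        p = ModelParams(k={"dpm": 0.0, "rpm": 0.0, "bio": 0.0, "hum": 0.0})
        state = PoolState(np.full((6, 4), 50.0))
        fc = np.array([la.water_capacity_fc for la in site_layers])
        out, flux = step_month(state, 10.0, fc, site_layers, p)
        np.testing.assert_array_equal(out.stocks, state.stocks)
        assert flux.rh_total == 0.0

    def test_partition_bookkeeping_dpm_only(self, params):
        from droughtsoc.profile import Layer, layer_capacities

        layers = layer_capacities(
            [Layer(1, 0.0, 5.0, 1000.0, clay=10.0)], "prescribed", [10.0]
        )
        p = single_layer_params()
        stocks = np.array([[500.0, 0.0, 0.0, 0.0]])
        out, flux = step_month(PoolState(stocks), p.t_ref, np.array([10.0]), layers, p)
        d_dpm = 500.0 - out.pool("dpm")[0]
        to_co2 = co2_partition_fraction(10.0, p.bio_fraction)[0]
        assert flux.rh[0, 0] / d_dpm == pytest.approx(to_co2, rel=1e-12)

    def test_mass_balance_exact(self, site_layers, params):
        rng = np.random.default_rng(3)
        state = PoolState(rng.uniform(0, 5000, (6, 4)))
        water = rng.uniform(0, 15, 6)
        out, flux = step_month(
            state, 12.0, water, site_layers, params, plant_c=300.0
        )
        d_soc = out.stocks.sum() - state.stocks.sum()
        assert d_soc == pytest.approx(300.0 - flux.rh_total, abs=1e-9)

    def test_nan_forcing_names_month(self, site_layers, params):
        state = PoolState(np.ones((6, 4)))
        with pytest.raises(ValueError, match="month index 17"):
            step_month(state, float("nan"), np.ones(6), site_layers, params,
                       month_index=17)


class TestSimulation:
    def test_pools_never_negative(self, site_layers, params):
        forcing = constant_forcing(120, p=100.0, temp=12.0, pet=60.0)
        init = PoolState(np.full((6, 4), 1000.0))
        res = run_simulation(forcing, np.full(120, 200.0), site_layers, params, init)
        assert np.all(res.pools >= 0)

    def test_carbon_conservation_along_run(self, site_layers, params):
        forcing = constant_forcing(240, p=110.0, temp=9.0, pet=55.0)
        init = PoolState(np.full((6, 4), 2000.0))
        res = run_simulation(forcing, np.full(240, 300.0), site_layers, params, init)
        resid = np.diff(res.soc_total()) + res.rh_monthly() - res.plant_inputs
        assert np.abs(resid).max() < 1e-6


class TestSpinup:
    def _steady_state_oracle(self, layers, params, monthly_input):
        """Solve the per-layer linear steady state s = A s + b directly."""
        k = params.k_vector()
        decay = 1.0 - np.exp(-k / 12.0)  # modifiers pinned at 1
        states = []
        for la, inp in zip(layers, monthly_input):
            f_co2, f_bio, f_hum = co2_partition_fraction(la.clay, params.bio_fraction)
            a = np.diag(1.0 - decay)
            a[2] += f_bio * decay  # every pool's loss feeds BIO
            a[3] += f_hum * decay
            r = params.dpm_rpm_ratio
            b = inp * np.array([r / (1 + r), 1 / (1 + r), 0.0, 0.0])
            states.append(np.linalg.solve(np.eye(4) - a, b))
        return np.array(states)

    def test_direct_matches_algebraic_steady_state(self, site_layers, params):
        block = optimum_forcing(12, site_layers, params)
        inputs = np.full(12, 250.0)
        state = spinup(site_layers, block, inputs, params)
        per_layer_input = 250.0 * np.array(params.depth_allocation)
        oracle = self._steady_state_oracle(site_layers, params, per_layer_input)
        np.testing.assert_allclose(state.stocks, oracle, rtol=1e-8)

    def test_homogeneity_in_inputs(self, site_layers, params):
        block = optimum_forcing(12, site_layers, params)
        s1 = spinup(site_layers, block, np.full(12, 100.0), params)
        s2 = spinup(site_layers, block, np.full(12, 200.0), params)
        np.testing.assert_allclose(s2.stocks, 2.0 * s1.stocks, rtol=1e-9)

    def test_rescale_to_target_is_identity_at_converged_soc(self, site_layers, params):
        block = optimum_forcing(12, site_layers, params)
        inputs = np.full(12, 250.0)
        free = spinup(site_layers, block, inputs, params)
        target = free.stocks.sum(axis=1)
        rescaled = spinup(site_layers, block, inputs, params, target_soc=target)
        np.testing.assert_allclose(rescaled.stocks, free.stocks, rtol=1e-12)

    def test_rescale_preserves_pool_proportions(self, site_layers, params):
        block = optimum_forcing(12, site_layers, params)
        inputs = np.full(12, 250.0)
        free = spinup(site_layers, block, inputs, params)
        target = 2.0 * free.stocks.sum(axis=1)
        scaled = spinup(site_layers, block, inputs, params, target_soc=target)
        np.testing.assert_allclose(scaled.stocks, 2.0 * free.stocks, rtol=1e-12)

    def test_iterate_agrees_with_direct(self, site_layers, params):
        block = optimum_forcing(12, site_layers, params)
        inputs = np.full(12, 250.0)
        direct = spinup(site_layers, block, inputs, params)
        iterated = spinup(
            site_layers, block, inputs, params, method="iterate", tol=1e-7,
            max_iter=20000,
        )
        np.testing.assert_allclose(iterated.stocks, direct.stocks, rtol=1e-3)

    def test_nonconvergence_reports_residual(self, site_layers, params):
        block = optimum_forcing(12, site_layers, params)
        with pytest.raises(SpinupError, match="residual"):
            spinup(site_layers, block, np.full(12, 250.0), params,
                   method="iterate", tol=1e-15, max_iter=3)
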