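import numpy as np
import pytest

from pericell import (
    ConsumptionParams,
    GasSchedule,
    MediaColumn,
    SolverOptions,
    TransportParams,
    axial_gradient,
    consumption_term,
    simulate_culture,
    simulate_diffusion,
    steady_state_profile,
)
from pericell.units import DEFAULT_CONSTANTS


class TestConsumptionTerm:
    def test_zero_substrate_means_zero_sink(self, col24, monolayer):
        c = np.zeros(16)
        assert np.all(consumption_term(c, monolayer, col24) == 0.0)
        sus = ConsumptionParams(density=1e5, mode="suspension")
        assert np.all(consumption_term(c, sus, col24) == 0.0)

    def test_saturation_recovers_areal_rate(self, col24, monolayer):
        # C >> Km: total sink equals density * vmax (converted units)
        c = np.full(32, 18.6)
        dx = col24.height_cm / 32
        total = -consumption_term(c, monolayer, col24).sum() * dx
        expected = monolayer.saturation_rate(DEFAULT_CONSTANTS)
        assert total == pytest.approx(expected, rel=0.01)

    def test_half_rate_at_km(self, col24, monolayer):
        km_pct = monolayer.km_percent(DEFAULT_CONSTANTS)
        c = np.full(32, km_pct)
        dx = col24.height_cm / 32
        total = -consumption_term(c, monolayer, col24).sum() * dx
        assert total == pytest.approx(0.5 * monolayer.saturation_rate(), rel=1e-9)

    def test_suspension_sink_is_uniform(self, col24):
        sus = ConsumptionParams(density=1e5, mode="suspension")
        sink = consumption_term(np.full(16, 18.6), sus, col24)
        assert np.ptp(sink) == pytest.approx(0.0, abs=1e-12)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown consumption mode"):
            ConsumptionParams(density=1.0, mode="biofilm")


class TestSimulateCulture:
    def test_zero_vmax_reduces_to_diffusion_bitwise(self, col24, transport, gas_1pct):
        t = np.linspace(0, 24, 97)
        none = ConsumptionParams(density=21000.0, vmax_amol_cell_s=0.0)
        culture = simulate_culture(col24, transport, none, gas_1pct, 18.6, t)
        diffusion = simulate_diffusion(col24, transport, 18.6, gas_1pct, t)
        assert np.array_equal(culture.field.c, diffusion.c)

    def test_monolayer_anoxia_within_5h(self, col24, transport, monolayer, gas_1pct):
        t = np.linspace(0, 12, 241)
        res = simulate_culture(col24, transport, monolayer, gas_1pct, 18.6, t)
        below = res.pericellular_percent < 0.5
        assert below.any()
        assert t[np.argmax(below)] <= 5.0

    def test_azide_event_relaxes_to_setpoint(self, col24, transport, monolayer):
        sched = GasSchedule(segments=((0.0, 5.0),), events=((24.0, 0.0),))
        t = np.linspace(0, 96, 385)
        res = simulate_culture(col24, transport, monolayer, sched, 5.0, t)
        pre = np.interp(23.9, t, res.pericellular_percent)
        assert pre < 1.0  # consuming culture sits far below the setpoint
        assert res.pericellular_percent[-1] == pytest.approx(5.0, abs=0.05)

    def test_dc_suspension_sustained_anoxia(self, transport, gas_5pct):
        column = MediaColumn.from_vessel("96-well", 0.2)
        dc = ConsumptionParams(density=750000.0, mode="suspension")
        t = np.linspace(0, 72, 721)
        res = simulate_culture(column, transport, dc, gas_5pct, 18.6, t)
        frac_anoxic = np.mean(res.pericellular_percent < 0.5)
        assert frac_anoxic >= 0.95

    def test_gradient_direction_and_non_negativity(
        self, col24, transport, monolayer, gas_5pct
    ):
        t = np.linspace(0, 48, 193)
        res = simulate_culture(col24, transport, monolayer, gas_5pct, 18.6, t)
        assert np.all(res.field.c >= 0.0)
        late = t > 5.0  # after the initial drawdown transient
        assert np.all(
            res.pericellular_percent[late] <= res.surface_percent[late] + 1e-9
        )

    def test_density_monotonically_lowers_pericellular(
        self, col24, transport, gas_5pct
    ):
        t = np.linspace(0, 24, 49)
        traces = []
        for density in (5000.0, 20000.0, 80000.0):
            params = ConsumptionParams(density=density)
            res = simulate_culture(col24, transport, params, gas_5pct, 18.6, t)
            traces.append(res.pericellular_percent)
        assert np.all(traces[1] <= traces[0] + 1e-6)
        assert np.all(traces[2] <= traces[1] + 1e-6)

    def test_extended_mass_balance_with_consumption(
        self, col24, transport, monolayer, gas_5pct
    ):
        t = np.linspace(0, 72, 1441)
        res = simulate_culture(col24, transport, monolayer, gas_5pct, 18.6, t)
        field = res.field
        content = field.column_content()
        influx = field.surface_flux()
        cum_in = np.concatenate(
            [[0.0], np.cumsum(0.5 * (influx[1:] + influx[:-1]) * np.diff(t))]
        )
        closure = (content - content[0]) - (cum_in - res.consumed_per_area)
        assert np.abs(closure).max() / content[0] < 0.005

    def test_event_outside_span_rejected(self, col24, transport, monolayer):
        sched = GasSchedule(segments=((0.0, 5.0),), events=((100.0, 0.0),))
        with pytest.raises(ValueError, match="outside the simulated span"):
            simulate_culture(
                col24, transport, monolayer, sched, 18.6, np.linspace(0, 72, 73)
            )


class TestSteadyState:
    def test_no_cells_uniform_at_setpoint(self, col24, transport):
        none = ConsumptionParams(density=0.0)
        _, c = steady_state_profile(col24, transport, none, 5.0)
        assert np.allclose(c, 5.0)

    def test_monolayer_flux_balance_oracle(self, col24, transport):
        # Zero-order regime: C >> Km everywhere, so F = density*vmax and the
        # two-resistance balance gives Cb = Cgas - F/kL - F*L/D exactly.
        params = ConsumptionParams(density=2000.0)
        f = params.saturation_rate()
        L = col24.height_cm
        cgas = 18.6
        cb_expected = cgas - f / transport.kl_cm_h - f * L / transport.d_cm2_h
        assert cb_expected > 3.0  # check the regime assumption
        x, c = steady_state_profile(col24, transport, params, cgas)
        slope = (c[-1] - c[0]) / (x[-1] - x[0])
        assert slope == pytest.approx(f / transport.d_cm2_h, rel=0.01)
        cb = c[0] - slope * x[0]
        assert cb == pytest.approx(cb_expected, rel=0.01)

    def test_suspension_parabolic_oracle(self, col24):
        # Uniform zero-order sink: C(x) = C(0) + R0 x^2 / (2D)
        transport = TransportParams(kl_cm_h=0.5)
        # Km pushed low so the sink is effectively zero-order everywhere
        params = ConsumptionParams(density=20000.0, mode="suspension", km_um=0.01)
        r0 = params.saturation_rate()
        d = transport.d_cm2_h
        L = col24.height_cm
        cgas = 18.6
        c_top = cgas - r0 * L / transport.kl_cm_h
        c_bottom = c_top - r0 * L**2 / (2 * d)
        assert c_bottom > 3.0  # zero-order regime holds
        x, c = steady_state_profile(col24, transport, params, cgas)
        expected = c_bottom + r0 * x**2 / (2 * d)
        assert np.abs(c - expected).max() < 0.02

    @pytest.mark.parametrize("mode,density", [("monolayer", 21000.0),
                                              ("suspension", 50000.0)])
    def test_bvp_and_long_time_integration_agree(
        self, col24, transport, mode, density
    ):
        params = ConsumptionParams(density=density, mode=mode)
        _, c_bvp = steady_state_profile(col24, transport, params, 5.0, method="bvp")
        _, c_int = steady_state_profile(
            col24, transport, params, 5.0, method="integrate"
        )
        assert np.abs(c_bvp - c_int).max() < 1e-3

    def test_unknown_method_rejected(self, col24, transport, monolayer):
        with pytest.raises(ValueError):
            steady_state_profile(col24, transport, monolayer, 5.0, method="magic")


class TestAxialGradient:
    def test_cell_free_culture_is_flat(self, col24, transport, gas_5pct):
        none = ConsumptionParams(density=0.0)
        t = np.linspace(0, 72, 145)
        res = simulate_culture(col24, transport, none, gas_5pct, 5.0, t)
        bottom, top = axial_gradient(res, 48.0)
        assert bottom == pytest.approx(5.0, abs=1e-6)
        assert top == pytest.approx(5.0, abs=1e-6)

    def test_consuming_culture_bottom_below_top(
        self, col24, transport, monolayer, gas_5pct
    ):
        t = np.linspace(0, 48, 97)
        res = simulate_culture(col24, transport, monolayer, gas_5pct, 18.6, t)
        bottom, top = axial_gradient(res, 36.0)
        assert bottom <= top

    def test_zero_order_gradient_matches_flux_balance(self, col24, transport):
        # top - bottom = F L / D when consumption is saturated
        params = ConsumptionParams(density=2000.0)
        t = np.linspace(0, 200, 401)
        res = simulate_culture(
            col24, transport, params, GasSchedule.constant(18.6), 18.6, t
        )
        bottom, top = axial_gradient(res, 200.0)
        f = params.saturation_rate()
        # surface value sits half a resistance above the top cell; compare
        # against the continuous-profile span
        expected = f * col24.height_cm / transport.d_cm2_h
        assert top - bottom == pytest.approx(expected, rel=0.05)

    def test_time_outside_range_rejected(self, col24, transport, monolayer, gas_5pct):
        t = np.linspace(0, 10, 21)
        res = simulate_culture(col24, transport, monolayer, gas_5pct, 18.6, t)
        with pytest.raises(ValueError):
            axial_gradient(res, 11.0)
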