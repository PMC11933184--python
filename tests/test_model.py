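import numpy as np
import pytest

from graftflow.model import (
    STATE_NAMES,
    diastole_duration,
    elastance_waveform,
    endo_epi_flow_ratio,
    initial_state,
    intramyocardial_pressure,
    layer_resistance,
    simulate,
    state_derivative,
)
from graftflow.parameters import build_default_parameters


class TestElastance:
    @pytest.mark.parametrize("T", [0.6, 0.8, 1.0])
    def test_peak_equals_emax_independent_of_period(self, T):
        t = np.linspace(0, T, 20001)
        e = elastance_waveform(t, T, E_max=2.5, E_min=0.06)
        assert e.max() == pytest.approx(2.5, rel=1e-6)
        assert e.min() == pytest.approx(0.06)

    def test_value_at_activation_onset_is_emin(self):
        assert elastance_waveform(0.0, 0.8, 2.5, 0.06) == pytest.approx(0.06)

    def test_periodicity_to_machine_precision(self):
        t = np.linspace(0, 0.8, 513)[:-1]
        a = elastance_waveform(t, 0.8, 2.5, 0.06)
        b = elastance_waveform(t + 0.8, 0.8, 2.5, 0.06)
        assert np.max(np.abs(a - b)) < 1e-12

    def test_smooth_first_derivative(self):
        t = np.linspace(0, 1.6, 160001)
        e = elastance_waveform(t, 0.8, 2.5, 0.06)
        de = np.diff(e) / np.diff(t)
        # a jump in e' would show as a spike in the second difference
        assert np.max(np.abs(np.diff(de))) < 1e-2

    def test_emax_not_above_emin_rejected(self):
        with pytest.raises(ValueError):
            elastance_waveform(0.1, 0.8, E_max=0.06, E_min=0.06)


class TestDiastoleDuration:
    def test_affine_evaluation_at_default_coefficients(self):
        assert diastole_duration(0.8, 0.8, -0.17) == pytest.approx(0.8 * 0.8 - 0.17)

    def test_diastolic_fraction_increases_with_period(self):
        frac = [diastole_duration(T) / T for T in (0.6, 0.8, 1.0, 1.2)]
        assert all(a < b for a, b in zip(frac, frac[1:]))

    def test_degenerate_coefficients_rejected(self):
        with pytest.raises(ValueError):
            diastole_duration(0.8, slope=1.0, intercept=0.0)  # T_dia == T

    def test_period_outside_supported_range_rejected(self):
        with pytest.raises(ValueError):
            diastole_duration(2.0)


class TestConstitutive:
    def test_layer_resistance_reference_point_and_inverse_square(self):
        assert layer_resistance(2.0, R0=5.0, V0=2.0) == pytest.approx(5.0)
        assert layer_resistance(1.0, R0=1.0, V0=2.0) == pytest.approx(4.0)

    def test_layer_resistance_strictly_decreasing_in_volume(self):
        rs = [layer_resistance(v, 1.0, 1.0) for v in (0.5, 1.0, 2.0, 10.0)]
        assert all(a > b for a, b in zip(rs, rs[1:]))
        assert rs[-1] < 0.02

    def test_layer_resistance_collapse_rejected(self):
        with pytest.raises(ValueError):
            layer_resistance(0.0, 1.0, 1.0)

    @pytest.mark.parametrize("depth,plv,expected", [(0.0, 80, 0.0), (1.0, 120, 120.0), (0.5, 100, 50.0)])
    def test_intramyocardial_pressure_linear_in_depth(self, depth, plv, expected):
        assert intramyocardial_pressure(plv, depth) == pytest.approx(expected)

    def test_intramyocardial_pressure_depth_bounds(self):
        with pytest.raises(ValueError):
            intramyocardial_pressure(100.0, 1.5)


class TestStateDerivative:
    def test_equilibrium_all_rates_zero(self, default_params):
        # all node pressures zero: every compartment at its unstressed volume,
        # ventricles at V0 (so p_lv = 0 regardless of elastance), no flows
        p = default_params
        y = np.zeros(len(STATE_NAMES))
        y[0], y[1] = p.V0_lv, p.V0_rv
        y[2], y[3] = p.V0_la, p.V0_ra
        y[4], y[5], y[6], y[7] = p.Vun_sa, p.Vun_sv, p.Vun_pa, p.Vun_pv
        from graftflow.model import layer_weights

        w = layer_weights(p.endo_epi_ratio)
        y[11:14] = p.V0_1 * w
        y[14:17] = p.venous_v0_factor * p.V0_1 * w
        y[18] = p.Vun_g
        dy = state_derivative(y, 0.55, p)  # diastole: elastance at E_min
        assert np.max(np.abs(dy)) < 1e-12

    def test_closed_loop_volume_conservation_at_random_states(self, default_params, rng):
        vol_idx = [0, 1, 2, 3, 4, 5, 6, 7, 11, 12, 13, 14, 15, 16, 18]
        y0 = initial_state(default_params)
        for _ in range(20):
            y = y0 * rng.uniform(0.8, 1.2, size=y0.shape)
            dy = state_derivative(y, rng.uniform(0, 0.8), default_params)
            assert abs(dy[vol_idx].sum()) < 1e-9

    def test_reverse_biased_valve_carries_no_flow(self, default_params):
        # LV volume at V0 -> p_lv = 0 < p_sa -> aortic valve branch closed:
        # the arterial node's only inflow is the (zero) valve flow
        y = initial_state(default_params)
        y[0] = default_params.V0_lv
        y[17] = 0.0
        dy = state_derivative(y, 0.55, default_params)
        q_sa, q_g = y[8], y[10]
        assert dy[4] == pytest.approx(-q_sa - q_g)


class TestSimulate:
    def test_converges_and_conserves_volume(self, default_run):
        assert default_run.converged
        assert default_run.periodicity_residual < 1e-3
        assert default_run.volume_drift < 1e-3

    def test_periodicity_residual_decreases_after_beat_3(self, default_run):
        # residual k compares beats k+1 and k+2; pairs lying fully after
        # beat 3 are r[3:], and from there the approach to the limit cycle
        # is monotone
        r = default_run.periodicity_residuals
        assert np.all(np.diff(r[3:]) <= 1e-12)

    def test_aortic_valve_is_unidirectional(self, default_run):
        assert default_run.signals["q_av"].min() >= 0.0

    def test_signals_share_the_time_grid(self, default_run):
        n = len(default_run.t)
        assert all(len(v) == n for v in default_run.signals.values())
        for times in default_run.events.values():
            assert np.all((times >= 0) & (times <= default_run.t[-1]))

    def test_graft_mean_flow_non_increasing_with_stenosis(self, stenosis_runs):
        means = {
            pct: run.signals["graft_flow"][-2000:].mean()
            for pct, run in stenosis_runs.items()
        }
        assert means[0.0] > means[50.0] > means[75.0]

    def test_zero_pct_vs_disabled_element_differ_only_by_viscous_offset(self, default_params):
        a = simulate(default_params.replace(stenosis_pct=0.0), n_beats=6)
        p_off = default_params.replace(stenosis_pct=0.0)
        p_off.stenosis_enabled = False
        b = simulate(p_off, n_beats=6)
        qa = a.signals["graft_flow"][-2000:]
        qb = b.signals["graft_flow"][-2000:]
        # the enabled element at 0 % retains its viscous (Poiseuille) term,
        # a ~1 mmHg·s/mL series resistance: small but nonzero flow offset
        assert np.abs(qa - qb).max() < 0.15 * np.abs(qb).max()
        assert not np.allclose(qa, qb)

    def test_no_pumping_when_elastance_nearly_flat(self, default_params):
        p = default_params.replace(E_max_lv=default_params.E_min_lv * 1.001,
                                   E_max_rv=default_params.E_min_rv * 1.001)
        res = simulate(p, n_beats=10)
        last = res.signals["q_av"][-2000:]
        assert np.abs(last).mean() < 1.0  # mL/s; essentially no output

    def test_too_coarse_step_rejected(self, default_params):
        with pytest.raises(ValueError):
            simulate(default_params, n_beats=4, dt=default_params.T / 100)

    def test_fewer_than_two_beats_rejected(self, default_params):
        with pytest.raises(ValueError):
            simulate(default_params, n_beats=1)


class TestEndoEpiRatio:
    def test_matches_independent_trapezoid_integration(self, default_run):
        T = default_run.params.T
        t = default_run.t
        mask = t >= t[-1] - T
        num = np.trapezoid(default_run.signals["q_endo"][mask], t[mask])
        den = np.trapezoid(default_run.signals["q_epi"][mask], t[mask])
        assert endo_epi_flow_ratio(default_run) == pytest.approx(num / den, rel=1e-12)

    def test_deeper_subendocardium_lowers_the_ratio(self, default_params):
        shallow = simulate(default_params, n_beats=8)
        p_deep = default_params.replace()
        p_deep.depth_fractions = (1 / 6, 0.5, 0.98)
        p_deep.validate()
        deep = simulate(p_deep, n_beats=8)
        assert endo_epi_flow_ratio(deep) < endo_epi_flow_ratio(shallow)
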