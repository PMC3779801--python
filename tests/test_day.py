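"""Within-day simulator: events, oracles, conservation properties."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from coopres import (CultureState, ModelParams, PassageProtocol,
                     analytic_no_antibiotic_day, sensitive_rate,
                     simulate_day)

from oracle import ode_day_fraction


def make_initial(f, N_i, A_i):
    return CultureState(0.0, f * N_i, (1.0 - f) * N_i, A_i)


class TestSensitiveRate:
    def test_growth_below_mic(self, params):
        assert sensitive_rate(0.0, 2.0, params) == params.gamma_S

    def test_death_above_mic_bactericidal(self, params):
        assert sensitive_rate(100.0, 2.0, params) == -2.8

    def test_lag_freezes_everything(self, params):
        assert sensitive_rate(100.0, 0.5, params) == 0.0

    def test_bacteriostatic_stalls_instead_of_killing(self):
        p = ModelParams(mode="bacteriostatic")
        assert sensitive_rate(100.0, 2.0, p) == 0.0

    def test_boundary_is_death(self, params):
        # A == MIC counts as above: tau_b is a strict down-crossing
        assert sensitive_rate(params.MIC, 2.0, params) == -params.gamma_D


class TestSimulateDay:
    def test_pure_resistant_closed_form(self, params, protocol):
        day = simulate_day(make_initial(1.0, 1e5, 100.0), params, protocol)
        assert day.f_final == 1.0
        expected_tsat = params.t_lag + math.log(protocol.D) / params.gamma_R
        assert day.t_sat == pytest.approx(expected_tsat, abs=1e-8)

    def test_no_degraders_pure_decay(self, params, protocol):
        day = simulate_day(make_initial(0.0, 1e5, 100.0), params, protocol)
        assert day.f_final == 0.0
        assert day.t_sat is None
        assert day.tau_b is None
        # death runs from lag end to the end of the day, A never moves
        expected = 1e5 * math.exp(-params.gamma_D * (protocol.T_day - params.t_lag))
        assert day.final_state.N_S == pytest.approx(expected, rel=1e-9)
        assert day.final_state.A == pytest.approx(100.0, rel=1e-12)

    @pytest.mark.parametrize("f0", [0.1, 0.3, 0.55, 0.9])
    def test_agrees_with_independent_ode_integration(self, f0, params, protocol):
        ours = simulate_day(make_initial(f0, 1e5, 100.0), params, protocol)
        ref = ode_day_fraction(f0, params, protocol, rtol=1e-10)
        assert ours.f_final == pytest.approx(ref, abs=2e-7)

    @pytest.mark.parametrize("f0", [1e-3, 0.25, 0.5, 0.9])
    @pytest.mark.parametrize("N_i", [1e4, 1e5, 5e5])
    def test_matches_no_antibiotic_closed_form(self, f0, N_i, params):
        proto = PassageProtocol(A_i=0.0, N_i=N_i)
        ini = make_initial(f0, N_i, 0.0)
        sim = simulate_day(ini, params, proto)
        ana = analytic_no_antibiotic_day(ini, params, proto)
        assert sim.f_final == pytest.approx(ana.f_final, rel=1e-6)
        assert sim.final_state.N_R == pytest.approx(ana.final_state.N_R, rel=1e-6)
        assert sim.final_state.N_S == pytest.approx(ana.final_state.N_S, rel=1e-6)
        if ana.t_sat is not None:
            assert sim.t_sat == pytest.approx(ana.t_sat, abs=1e-6)

    def test_two_strain_saturation_time_closed_form(self, params):
        # e^{gR u} + e^{gS u} = 2*N_sat/N_i, t_sat = t_lag + u
        proto = PassageProtocol(A_i=0.0, N_i=1e5)
        day = simulate_day(make_initial(0.5, 1e5, 0.0), params, proto)
        u = brentq(lambda x: (math.exp(params.gamma_R * x)
                              + math.exp(params.gamma_S * x)
                              - 2.0 * params.N_sat / 1e5), 0.0, 10.0,
                   xtol=1e-12)
        assert day.t_sat == pytest.approx(params.t_lag + u, abs=1e-8)
        assert day.t_sat == pytest.approx(1.0 + 3.85, abs=5e-3)

    def test_analytic_day_rejects_antibiotic(self, params, protocol):
        with pytest.raises(ValueError):
            analytic_no_antibiotic_day(make_initial(0.5, 1e5, 100.0),
                                       params, protocol)

    def test_mic_crossing_event_location(self, params, protocol):
        day = simulate_day(make_initial(0.3, 1e5, 100.0), params, protocol)
        assert day.tau_b is not None
        state = day.state_at(day.tau_b)
        assert state.A == pytest.approx(params.MIC, abs=1e-8)

    def test_dose_at_or_below_mic_means_no_death_day(self, params):
        proto = PassageProtocol(A_i=1.1)
        day = simulate_day(make_initial(0.3, 1e5, 1.1), params, proto)
        assert day.tau_b == 0.0
        # nobody died: strictly fewer resistant than inoculated fraction
        assert day.f_final < 0.3

    def test_antibiotic_monotone_along_trajectory(self, params, protocol):
        day = simulate_day(make_initial(0.2, 1e5, 100.0), params, protocol)
        A = [s.A for s in day.trajectory]
        assert all(a1 >= a2 - 1e-9 for a1, a2 in zip(A, A[1:]))
        assert A[0] - A[-1] <= 100.0 + 1e-9

    def test_resistant_nondecreasing_after_lag(self, params, protocol):
        day = simulate_day(make_initial(0.2, 1e5, 100.0), params, protocol)
        NR = [s.N_R for s in day.trajectory if s.t >= params.t_lag]
        assert all(b >= a * (1 - 1e-12) for a, b in zip(NR, NR[1:]))

    def test_degradation_budget_identity(self, params, protocol):
        # integral of V_max*N_R over [0, tau_b] must equal
        # (A_i - MIC) + K_eff*ln(A_i/MIC): the separable MM budget
        day = simulate_day(make_initial(0.25, 1e5, 100.0), params, protocol)
        assert day.tau_b is not None
        spent, _ = quad(lambda t: params.V_max * day.state_at(t).N_R,
                        0.0, day.tau_b, limit=200)
        K_eff = protocol.k_eff(params)
        budget = (100.0 - params.MIC) + K_eff * math.log(100.0 / params.MIC)
        assert spent == pytest.approx(budget, rel=0.01)

    def test_tolerance_refinement_stable(self, params, protocol):
        a = simulate_day(make_initial(0.37, 1e5, 100.0), params, protocol,
                         root_tol=1e-12)
        b = simulate_day(make_initial(0.37, 1e5, 100.0), params, protocol,
                         root_tol=5e-13)
        assert abs(a.f_final - b.f_final) < 1e-6

    def test_cost_of_resistance_below_mic(self, params):
        proto = PassageProtocol(A_i=0.5)  # below MIC the whole day
        for f0 in (0.2, 0.5, 0.8):
            day = simulate_day(make_initial(f0, 1e5, 0.5), params, proto)
            assert day.f_final < f0

    def test_bacteriostatic_spares_sensitive_cells(self, protocol):
        p = ModelParams(mode="bacteriostatic")
        day = simulate_day(make_initial(0.1, 1e5, 100.0), p, protocol)
        NS = [s.N_S for s in day.trajectory]
        assert all(b >= a * (1 - 1e-12) for a, b in zip(NS, NS[1:]))

    def test_invalid_inputs(self, params, protocol):
        with pytest.raises(ValueError):
            simulate_day(CultureState(1.0, 1e4, 1e4, 100.0), params, protocol)
        with pytest.raises(ValueError):
            simulate_day(make_initial(0.5, 2e7, 100.0), params,
                         PassageProtocol(N_i=2e7))
        with pytest.raises(ValueError):
            simulate_day(make_initial(0.5, 1e5, 100.0), params,
                         PassageProtocol(T_day=0.8))

    def test_trajectory_export_columns(self, params, protocol):
        day = simulate_day(make_initial(0.3, 1e5, 100.0), params, protocol)
        df = day.to_frame()
        assert list(df.columns) == ["t_h", "N_R_per_ul", "N_S_per_ul",
                                    "A_ug_ml"]
        assert df["t_h"].is_monotonic_increasing
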