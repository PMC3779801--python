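"""Closed-form equilibrium, scaling collapse, oscillations, saturation."""

import math

import numpy as np
import pytest

from coopres import (EquilibriumResult, ModelParams, PassageProtocol,
                     analytic_equilibrium, collapse_check, find_equilibrium,
                     oscillation_scan, saturation_time_profile)


def hand_equilibrium(params, protocol):
    """Independent re-derivation of the fixed-point conditions."""
    gR, gS, gD = params.gamma_R, params.gamma_S, params.gamma_D
    growth_window = math.log(protocol.D) / gR
    dt = (gS - gR) * growth_window / (gS + gD)
    K_eff = params.K_M * (1.0 + protocol.I / params.K_I)
    budget = (protocol.A_i - params.MIC) + K_eff * math.log(
        protocol.A_i / params.MIC)
    N_i = params.N_sat / protocol.D if protocol.N_i is None else protocol.N_i
    exposure = params.t_lag + (math.exp(gR * dt) - 1.0) / gR
    return budget / (params.V_max * N_i * exposure), dt


class TestAnalyticEquilibrium:
    def test_hand_value_at_reference_condition(self, params, protocol):
        f, dt = hand_equilibrium(params, protocol)
        assert dt == pytest.approx(0.17, abs=5e-3)
        assert f == pytest.approx(0.52, abs=5e-3)
        assert analytic_equilibrium(params, protocol) == pytest.approx(
            f, rel=1e-12)

    def test_undefined_at_or_below_mic(self, params):
        with pytest.raises(ValueError):
            analytic_equilibrium(params, PassageProtocol(A_i=1.0))

    def test_matches_simulated_fixed_point(self, params):
        # the fold-growth + budget conditions are exact for this map
        for A in (27.0, 50.0, 100.0, 200.0):
            for D in (100.0, 200.0, 800.0):
                proto = PassageProtocol(A_i=A, D=D)
                fa = analytic_equilibrium(params, proto)
                eq = find_equilibrium(params, proto)
                if eq.interior:
                    assert fa == pytest.approx(eq.f_star, rel=0.10)

    def test_approximately_doubles_with_dose(self, params):
        f1 = analytic_equilibrium(params, PassageProtocol(A_i=100.0))
        f2 = analytic_equilibrium(params, PassageProtocol(A_i=200.0))
        assert f2 / f1 == pytest.approx(2.0, rel=0.15)

    def test_inversely_proportional_to_inoculum(self, params):
        base = PassageProtocol(A_i=50.0, N_i=1e5)
        half = PassageProtocol(A_i=50.0, N_i=5e4)
        assert analytic_equilibrium(params, half) == pytest.approx(
            2.0 * analytic_equilibrium(params, base), rel=1e-9)

    def test_first_order_parameter_insensitivity(self, params, protocol):
        # elasticity |d ln f* / d ln theta| < 1 for lag, death rate, cost
        base = analytic_equilibrium(params, protocol)
        d = 0.05

        def elasticity(make):
            up = analytic_equilibrium(make(1 + d), protocol)
            dn = analytic_equilibrium(make(1 - d), protocol)
            return (up - dn) / (2 * d * base)

        e_lag = elasticity(lambda s: params.replace(t_lag=params.t_lag * s))
        e_dth = elasticity(lambda s: params.replace(gamma_D=params.gamma_D * s))
        e_cost = elasticity(lambda s: params.replace(
            gamma_S=params.gamma_R + s * params.cost))
        for e in (e_lag, e_dth, e_cost):
            assert abs(e) < 1.0

    def test_halfway_robust_to_death_rate_and_cost(self, params, protocol):
        # +-50% changes in gamma_D and the cost move f* by far less
        base = analytic_equilibrium(params, protocol)
        for s in (0.5, 1.5):
            f_d = analytic_equilibrium(
                params.replace(gamma_D=params.gamma_D * s), protocol)
            f_c = analytic_equilibrium(
                params.replace(gamma_S=params.gamma_R + s * params.cost),
                protocol)
            assert abs(f_d - base) / base < 0.5
            assert abs(f_c - base) / base < 0.5


@pytest.fixture(scope="module")
def model_equilibria(params):
    return [find_equilibrium(params, PassageProtocol(A_i=A, D=D))
            for A in (12.5, 25.0, 50.0, 100.0, 200.0)
            for D in (100.0, 200.0, 400.0, 800.0)]


@pytest.fixture(scope="module")
def scan(params, protocol):
    return oscillation_scan(params, protocol,
                            [200.0, 150.0, 100.0, 50.0, 25.0, 12.0, 6.0])


class TestCollapse:
    def test_equilibrium_density_same_across_dilutions(self, params):
        # N_R_eq at fixed dose varies < 5% around its mean across D
        for A in (27.0, 50.0):
            vals = [find_equilibrium(params,
                                     PassageProtocol(A_i=A, D=D)).N_R_eq
                    for D in (100.0, 200.0, 400.0, 800.0)]
            interior = [v for v, D in zip(vals, (100.0, 200.0, 400.0, 800.0))
                        if find_equilibrium(
                            params, PassageProtocol(A_i=A, D=D)).interior]
            m = np.mean(interior)
            assert all(abs(v - m) / m < 0.05 for v in interior)

    def test_pooled_fit_positive_slope(self, params, model_equilibria):
        sf = collapse_check(model_equilibria, params)
        assert sf.slope > 0
        assert sf.out_of_regime  # 12.5 ug/ml < 4*K_M is included
        assert sf.n_boundary_excluded > 0

    def test_exact_proportionality_gives_zero_residual(self, params):
        eqs = [EquilibriumResult(f_star=0.001 * A, N_R_eq=500.0 * A,
                                 lam=0.0, classification="stable-monotone",
                                 protocol=PassageProtocol(A_i=A))
               for A in (27.0, 54.0, 108.0, 216.0)]
        sf = collapse_check(eqs, params)
        assert sf.max_relative_residual == pytest.approx(0.0, abs=1e-12)
        assert not sf.out_of_regime

    def test_preconditions(self, params):
        few = [EquilibriumResult(0.3, 30.0, 0.0, "stable-monotone",
                                 PassageProtocol(A_i=50.0))] * 3
        with pytest.raises(ValueError):
            collapse_check(few, params)
        narrow = [EquilibriumResult(0.3, 30.0, 0.0, "stable-monotone",
                                    PassageProtocol(A_i=A))
                  for A in (50.0, 60.0, 70.0, 80.0)]
        with pytest.raises(ValueError):
            collapse_check(narrow, params)


class TestOscillationScan:
    def test_requires_descending_doses_above_mic(self, params, protocol):
        with pytest.raises(ValueError):
            oscillation_scan(params, protocol, [50.0, 100.0])
        with pytest.raises(ValueError):
            oscillation_scan(params, protocol, [100.0, 1.0])

    def test_multiplier_increases_with_dose(self, scan):
        lam = scan["lam"].to_numpy()[::-1]  # ascending A
        assert np.all(np.diff(lam) > 0)

    def test_stable_fixed_points_have_zero_amplitude(self, scan):
        stable = scan[np.abs(scan["lam"]) < 1.0]
        assert len(stable) > 0
        assert np.all(stable["amplitude"] == 0.0)

    def test_instability_appears_at_low_doses(self, scan):
        unstable = scan[np.abs(scan["lam"]) >= 1.0]
        assert len(unstable) > 0
        assert unstable["A_ug_ml"].max() < scan["A_ug_ml"].max()
        assert np.all(unstable["amplitude"] > 0.0)


class TestSaturationProfile:
    def test_pure_resistant_closed_form(self, params, protocol):
        prof = saturation_time_profile(params, protocol, [1.0])
        expected = params.t_lag + math.log(protocol.D) / params.gamma_R
        assert prof.t_sat[0] == pytest.approx(expected, abs=1e-8)

    def test_fastest_saturation_is_interior(self, params, protocol):
        grid = np.linspace(0.05, 1.0, 39)
        prof = saturation_time_profile(params, protocol, grid)
        assert 0.0 < prof.f_min < 1.0
        assert prof.t_min < prof.t_sat[-1]  # beats the pure-resistant culture
        f_star = find_equilibrium(params, protocol).f_star
        spacing = grid[1] - grid[0]
        assert abs(prof.f_min - f_star) > spacing

    def test_unreached_saturation_excluded(self, params):
        proto = PassageProtocol(A_i=100.0, T_day=6.0)
        prof = saturation_time_profile(params, proto, [0.01, 1.0])
        assert np.isnan(prof.t_sat[0])
        assert prof.f_min == 1.0

    def test_grid_validation(self, params, protocol):
        with pytest.raises(ValueError):
            saturation_time_profile(params, protocol, [0.0, 0.5])
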