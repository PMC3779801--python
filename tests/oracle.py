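"""Independent brute-force integrator used as a cross-check oracle.

Integrates the same within-day model with scipy's LSODA and terminal
events, sharing no code with the package's piecewise-analytic
propagator.  Slow but impartial.
"""

import math

from scipy.integrate import solve_ivp

from coopres import ModelParams, PassageProtocol


def ode_day_fraction(f0: float, params: ModelParams,
                     protocol: PassageProtocol, rtol: float = 1e-11) -> float:
    """Final resistant fraction after one day, by direct ODE integration."""
    N_i = protocol.inoculum(params)
    K_eff = protocol.k_eff(params)
    NR, NS, A = f0 * N_i, (1.0 - f0) * N_i, protocol.A_i
    t, T = 0.0, protocol.T_day
    sat = NR + NS >= params.N_sat
    below = A < params.MIC
    while t < T - 1e-10:
        in_lag = t < params.t_lag - 1e-10
        rR = params.gamma_R if (not in_lag and not sat) else 0.0
        if in_lag:
            rS = 0.0
        elif not below:
            rS = -params.death_rate
        else:
            rS = params.gamma_S if not sat else 0.0

        def rhs(tt, y):
            dA = -params.V_max * y[0] * y[2] / (K_eff + y[2]) if y[2] > 0 else 0.0
            return [rR * y[0], rS * y[1], dA]

        events = []
        if in_lag:
            ev = lambda tt, y: tt - params.t_lag
            ev.terminal = True
            events.append(ev)
        if not below:
            ev2 = lambda tt, y: y[2] - params.MIC
            ev2.terminal = True
            ev2.direction = -1
            events.append(ev2)
        if not sat and (rR > 0 or rS > 0):
            ev3 = lambda tt, y: y[0] + y[1] - params.N_sat
            ev3.terminal = True
            ev3.direction = 1
            events.append(ev3)
        sol = solve_ivp(rhs, [t, T], [NR, NS, A], rtol=rtol,
                        atol=[1e-8, 1e-8, 1e-13], events=events,
                        method="LSODA")
        NR, NS, A = sol.y[:, -1]
        t = sol.t[-1]
        if not below and A <= params.MIC * (1 + 1e-9):
            below = True
            A = min(A, params.MIC)
        if not sat and NR + NS >= params.N_sat * (1 - 1e-9):
            sat = True
            s = params.N_sat / (NR + NS)
            NR *= s
            NS *= s
    return NR / (NR + NS)
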