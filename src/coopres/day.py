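"""Within-day growth/death/degradation dynamics of one serial-dilution cycle.

The model tracks resistant density ``N_R`` (cells/µl), sensitive density
``N_S`` and the extracellular antibiotic concentration ``A`` (µg/ml) over
one growth cycle:

* during the lag phase ``t < t_lag`` neither strain divides nor dies, but
  resistant cells hydrolyse the antibiotic;
* after the lag, resistant cells grow at ``γ_R`` until the total density
  reaches ``N_sat``; sensitive cells grow at ``γ_S > γ_R`` while
  ``A < MIC`` and die at ``γ_D`` while ``A ≥ MIC`` (a bacteriostatic
  antibiotic stalls them instead of killing);
* the antibiotic decays by Michaelis–Menten bulk kinetics
  ``dA/dt = −V_max · N_R · A / (K_eff + A)`` at all times.

Because the per-capita rates are piecewise constant, the densities are
exponentials within each phase and the antibiotic obeys the separable
implicit solution ``A + K_eff ln A = A0 + K_eff ln A0 − degraded(τ)``.
The simulator therefore propagates the state analytically from event to
event (lag end, MIC down-crossing, saturation) with scalar root-finding,
which makes final fractions reproducible far beyond the 6 digits needed
for map derivatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .params import ModelParams, PassageProtocol

__all__ = [
    "CultureState",
    "DayResult",
    "sensitive_rate",
    "simulate_day",
    "analytic_no_antibiotic_day",
]

# state-space event tolerance and time tolerance, see module docstring
_STATE_TOL = 1e-9
_TIME_TOL = 1e-8


@dataclass(frozen=True)
class CultureState:
    """Instantaneous culture state: time (h), densities (cells/µl), A (µg/ml)."""

    t: float
    N_R: float
    N_S: float
    A: float

    def __post_init__(self) -> None:
        if self.t < 0 or self.N_R < -_STATE_TOL or self.N_S < -_STATE_TOL or self.A < -_STATE_TOL:
            raise ValueError(f"negative state component: {self}")

    @property
    def N_tot(self) -> float:
        return self.N_R + self.N_S

    @property
    def f(self) -> float:
        """Resistant fraction; 0 for an empty culture."""
        tot = self.N_tot
        return self.N_R / tot if tot > 0 else 0.0


@dataclass(frozen=True)
class _Phase:
    """One interval of constant per-capita rates, with closed-form state."""

    t0: float
    t1: float
    N_R0: float
    N_S0: float
    A0: float
    r_R: float
    r_S: float
    K_eff: float
    V_max: float
    root_tol: float = 1e-13

    def degraded(self, tau: float) -> float:
        """Cumulative degradation capacity over [t0, t0+tau], µg/ml."""
        if self.N_R0 <= 0:
            return 0.0
        if self.r_R == 0.0:
            return self.V_max * self.N_R0 * tau
        return self.V_max * self.N_R0 * math.expm1(self.r_R * tau) / self.r_R

    def antibiotic_at(self, tau: float) -> float:
        return _antibiotic_after(self.A0, self.K_eff, self.degraded(tau),
                                 self.root_tol)

    def state_at(self, t: float) -> CultureState:
        tau = t - self.t0
        return CultureState(
            t=t,
            N_R=self.N_R0 * math.exp(self.r_R * tau),
            N_S=self.N_S0 * math.exp(self.r_S * tau),
            A=self.antibiotic_at(tau),
        )


def _antibiotic_after(A0: float, K_eff: float, C: float, tol: float) -> float:
    """Solve A + K_eff ln A = A0 + K_eff ln A0 − C for A in (0, A0]."""
    if C <= 0.0 or A0 <= 0.0:
        return A0
    target = A0 + K_eff * math.log(A0) - C
    if target / K_eff < -600.0:
        return 0.0
    g = lambda a: a + K_eff * math.log(a) - target
    # g is strictly increasing with g(A0) = C > 0; grow the bracket down
    lo = A0 * 0.5
    while g(lo) > 0.0:
        lo *= 0.5
        if lo < 1e-280:
            return 0.0
    return brentq(g, lo, A0, xtol=tol, rtol=4 * np.finfo(float).eps)


def sensitive_rate(A: float, t: float, params: ModelParams) -> float:
    """Per-capita sensitive-cell rate (/h) at antibiotic level ``A``, time ``t``.

    Zero during lag; ``+γ_S`` below MIC; ``−γ_D`` at or above MIC for a
    bactericidal antibiotic, 0 for a bacteriostatic one.  Saturation
    gating is the simulator's job, not this function's.
    """
    if A < 0 or t < 0:
        raise ValueError("A and t must be >= 0")
    if t < params.t_lag:
        return 0.0
    if A < params.MIC:
        return params.gamma_S
    return -params.death_rate


def simulate_day(initial: CultureState, params: ModelParams,
                 protocol: PassageProtocol, root_tol: float = 1e-13) -> "DayResult":
    """Propagate one growth cycle of length ``protocol.T_day``.

    Parameters
    ----------
    initial : CultureState
        State at inoculation; ``initial.t`` must be 0 and ``initial.A``
        equal to the protocol's daily antibiotic dose.
    root_tol : float
        Absolute tolerance of the scalar root solves used for event
        location and the implicit antibiotic solution.

    Returns
    -------
    DayResult
        Phases, event times (``tau_b``, ``t_sat``), final state and
        final resistant fraction.
    """
    if initial.t != 0.0:
        raise ValueError("initial state must have t=0")
    protocol.validate_against(params)
    T = protocol.T_day
    K_eff = protocol.k_eff(params)
    MIC = params.MIC
    V_max = params.V_max
    N_sat = params.N_sat
    mode_cidal = params.mode == "bactericidal"

    t = 0.0
    N_R, N_S, A = initial.N_R, initial.N_S, initial.A
    if N_R + N_S > N_sat * (1 + _STATE_TOL):
        raise ValueError("initial density exceeds N_sat")
    saturated = N_R + N_S >= N_sat * (1 - _STATE_TOL)
    # convention: a day that starts at or below MIC has tau_b = 0 and no
    # death phase at all
    below_mic = A <= MIC
    tau_b: float | None = 0.0 if below_mic else None
    t_sat: float | None = 0.0 if saturated else None
    phases: list[_Phase] = []

    while t < T - _TIME_TOL:
        in_lag = t < params.t_lag - _TIME_TOL
        r_R = params.gamma_R if (not in_lag and not saturated) else 0.0
        if in_lag:
            r_S = 0.0
        elif not below_mic:
            r_S = -params.gamma_D if mode_cidal else 0.0
        else:
            r_S = params.gamma_S if not saturated else 0.0

        # candidate events: (tau, kind); the earliest wins
        events: list[tuple[float, str]] = [(T - t, "end")]
        if in_lag:
            events.append((params.t_lag - t, "lag"))
        if not below_mic and N_R > 0 and A > MIC:
            budget = (A - MIC) + K_eff * math.log(A / MIC)
            if r_R == 0.0:
                tau_mic = budget / (V_max * N_R)
            else:
                tau_mic = math.log1p(r_R * budget / (V_max * N_R)) / r_R
            events.append((tau_mic, "mic"))
        if not saturated and (r_R > 0.0 or r_S > 0.0):
            h = lambda u: (N_R * math.exp(r_R * u)
                           + N_S * math.exp(r_S * u) - N_sat)
            if h(T - t) >= 0.0:
                hi = min(1.0, T - t)
                while h(hi) < 0.0:
                    hi = min(hi * 2.0, T - t)
                events.append((brentq(h, 0.0, hi, xtol=root_tol), "sat"))

        tau, kind = min(events, key=lambda e: e[0])
        tau = max(tau, 0.0)
        A_new = _antibiotic_after(A, K_eff, self_deg := (
            V_max * N_R * tau if r_R == 0.0
            else V_max * N_R * math.expm1(r_R * tau) / r_R), root_tol)
        phases.append(_Phase(t, t + tau, N_R, N_S, A, r_R, r_S, K_eff,
                             V_max, root_tol))
        N_R *= math.exp(r_R * tau)
        N_S *= math.exp(r_S * tau)
        t += tau
        A = A_new
        if kind == "mic":
            A = MIC
            below_mic = True
            tau_b = t
        elif kind == "sat":
            saturated = True
            t_sat = t
            # snap to the saturation manifold within event tolerance
            N_scale = N_sat / (N_R + N_S)
            N_R *= N_scale
            N_S *= N_scale
        elif kind == "lag" and not below_mic and A <= MIC:
            below_mic = True
            tau_b = t
        if not below_mic and A <= MIC:
            below_mic = True
            if tau_b is None:
                tau_b = t
        if not math.isfinite(N_R) or not math.isfinite(N_S) or not math.isfinite(A):
            raise FloatingPointError(f"non-finite state at t={t}")

    final = CultureState(T, N_R, N_S, A)
    if initial.A > MIC and below_mic is False:
        tau_b = None
    return DayResult(phases=phases, tau_b=tau_b, t_sat=t_sat,
                     final_state=final, f_final=final.f)


@dataclass
class DayResult:
    """Outcome of one growth cycle.

    ``tau_b`` is the time (h) at which the antibiotic first drops below
    the MIC (0 by convention if the day starts at or below MIC, ``None``
    if it never does); ``t_sat`` the time the culture saturates (``None``
    if it does not within the day).
    """

    phases: list[_Phase]
    tau_b: float | None
    t_sat: float | None
    final_state: CultureState
    f_final: float
    _traj: list[CultureState] | None = field(default=None, repr=False)

    def state_at(self, t: float) -> CultureState:
        """Closed-form state at any time within the day."""
        if not self.phases:
            return self.final_state
        if t >= self.phases[-1].t1:
            return self.final_state if t >= self.final_state.t else \
                self.phases[-1].state_at(t)
        for ph in self.phases:
            if t <= ph.t1:
                return ph.state_at(max(t, ph.t0))
        return self.final_state

    @property
    def trajectory(self) -> list[CultureState]:
        """Time-ordered states: a uniform grid plus all event boundaries."""
        if self._traj is None:
            T = self.final_state.t
            times = set(np.linspace(0.0, T, 201))
            for ph in self.phases:
                times.add(ph.t0)
                times.add(ph.t1)
            self._traj = [self.state_at(t) for t in sorted(times)]
        return self._traj

    def to_frame(self):
        """Trajectory as a DataFrame with canonical column names."""
        import pandas as pd

        return pd.DataFrame(
            {
                "t_h": [s.t for s in self.trajectory],
                "N_R_per_ul": [s.N_R for s in self.trajectory],
                "N_S_per_ul": [s.N_S for s in self.trajectory],
                "A_ug_ml": [s.A for s in self.trajectory],
            }
        )


def analytic_no_antibiotic_day(initial: CultureState, params: ModelParams,
                               protocol: PassageProtocol) -> DayResult:
    """Exact two-exponential solution for an antibiotic-free day.

    Both strains sit through the lag, then grow exponentially (sensitive
    faster, by the cost of resistance) until the total density reaches
    ``N_sat``; the saturation time is located by scalar root-finding.
    Serves as an integration oracle for :func:`simulate_day`.
    """
    if initial.A != 0.0:
        raise ValueError("analytic_no_antibiotic_day requires initial.A == 0")
    protocol.validate_against(params)
    T = protocol.T_day
    gR, gS, t_lag = params.gamma_R, params.gamma_S, params.t_lag
    N_R0, N_S0 = initial.N_R, initial.N_S
    N_sat = params.N_sat

    def total(u: float) -> float:  # u = time after lag
        return N_R0 * math.exp(gR * u) + N_S0 * math.exp(gS * u)

    t_sat: float | None = None
    if N_R0 + N_S0 >= N_sat:
        t_sat = 0.0
        u_end = 0.0
    elif total(T - t_lag) >= N_sat:
        u_sat = brentq(lambda u: total(u) - N_sat, 0.0, T - t_lag,
                       xtol=1e-13)
        t_sat = t_lag + u_sat
        u_end = u_sat
    else:
        u_end = T - t_lag
    N_R = N_R0 * math.exp(gR * u_end)
    N_S = N_S0 * math.exp(gS * u_end)
    final = CultureState(T, N_R, N_S, 0.0)
    phases = [
        _Phase(0.0, t_lag, N_R0, N_S0, 0.0, 0.0, 0.0, params.K_M, 0.0),
        _Phase(t_lag, t_lag + u_end, N_R0, N_S0, 0.0, gR, gS, params.K_M, 0.0),
    ]
    if t_sat is not None and t_lag + u_end < T:
        phases.append(_Phase(t_lag + u_end, T, N_R, N_S, 0.0, 0.0, 0.0,
                             params.K_M, 0.0))
    return DayResult(phases=phases, tau_b=0.0, t_sat=t_sat,
                     final_state=final, f_final=final.f)
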