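"""Analytic layer: closed-form equilibrium, scaling collapse, oscillations.

The interior fixed point of the daily map can be approximated in closed
form from two conditions that hold at equilibrium:

1. *Equal fold-growth.*  Over one cycle both strains must grow by the
   dilution factor ``D``.  Resistant cells grow at ``γ_R`` from the end
   of the lag until saturation, so the growth window is
   ``T − t_lag = ln(D)/γ_R``; equating the sensitive strain's net fold
   (death at ``γ_D`` for a window ``Δt``, growth at ``γ_S`` afterwards)
   gives ``Δt = (γ_S − γ_R)(T − t_lag)/(γ_S + γ_D)``.

2. *Antibiotic budget.*  Separating the Michaelis–Menten rate law, the
   degradation capacity spent bringing the dose ``A_i`` down to the MIC
   is ``∫ V_max·N_R dt = (A_i − MIC) + K_eff·ln(A_i/MIC)``.  With
   ``N_R = f·N_i`` constant through the lag and growing at ``γ_R`` for
   the death window ``Δt``, solving for ``f`` yields

   ``f* = [(A_i − MIC) + K_eff·ln(A_i/MIC)]
          / (V_max·N_i·[t_lag + (e^{γ_R·Δt} − 1)/γ_R])``.

Hence ``f*`` is approximately linear in ``A_i`` (for ``A_i ≫ K_eff``),
inversely proportional to the inoculum density ``N_i``, linear in the
inhibitor concentration through ``K_eff``, and insensitive to the lag,
the death rate and the cost of resistance, which only enter through the
weak ``Δt`` dependence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .day import CultureState, simulate_day
from .params import ModelParams, PassageProtocol
from .passage import EquilibriumResult, find_equilibrium, step_map

__all__ = [
    "ScalingFit",
    "SaturationProfile",
    "analytic_equilibrium",
    "collapse_check",
    "oscillation_scan",
    "saturation_time_profile",
]

# orbit length and tail window for limit-cycle amplitude detection
ORBIT_LENGTH = 200
ORBIT_TAIL = 20


def analytic_equilibrium(params: ModelParams,
                         protocol: PassageProtocol) -> float:
    """Closed-form equilibrium resistant fraction, clipped to [0, 1].

    Requires an antibiotic dose above the MIC (otherwise there is no
    death window and no interior equilibrium).
    """
    A_i = protocol.A_i
    if A_i <= params.MIC:
        raise ValueError(
            f"analytic equilibrium undefined for A_i={A_i} <= MIC={params.MIC}")
    K_eff = protocol.k_eff(params)
    gR, gS, gD = params.gamma_R, params.gamma_S, params.gamma_D
    growth_window = math.log(protocol.D) / gR
    dt_death = (gS - gR) * growth_window / (gS + gD)
    budget = (A_i - params.MIC) + K_eff * math.log(A_i / params.MIC)
    N_i = protocol.inoculum(params)
    exposure = params.t_lag + math.expm1(gR * dt_death) / gR
    f = budget / (params.V_max * N_i * exposure)
    return float(np.clip(f, 0.0, 1.0))


@dataclass
class ScalingFit:
    """Least-squares line of equilibrium resistant density vs dose.

    The model predicts the equilibrium *number* of resistant cells in the
    inoculum, ``N_R_eq = f*·N_i``, to depend on the antibiotic dose alone
    — pooling conditions across dilution factors should collapse onto a
    single line.
    """

    slope: float                 # (cells/µl)/(µg/ml)
    intercept: float             # cells/µl
    max_relative_residual: float
    n_conditions: int
    out_of_regime: bool = False  # True if points with A_i < 4·K_eff included
    n_boundary_excluded: int = 0  # conditions at f*∈{0,1} dropped from the fit

    def predict(self, A_i):
        return self.slope * np.asarray(A_i) + self.intercept


def collapse_check(equilibria: Iterable[EquilibriumResult],
                   params: ModelParams) -> ScalingFit:
    """Fit N_R_eq vs A_i pooled across dilution factors.

    Requires at least 4 interior equilibria spanning close to a decade
    (≥7×) in dose — the canonical dose designs span 7.4–16× once
    fully-resistant conditions drop out.  Boundary attractors (fully sensitive or fully
    resistant conditions) carry no scaling information and are excluded,
    with their count reported.  Conditions with ``A_i < 4·K_eff`` are
    admitted but flag the fit as out-of-regime (Michaelis–Menten
    curvature bends the line there).
    """
    all_eqs = list(equilibria)
    eqs = [e for e in all_eqs if e.interior and 0.0 < e.f_star < 1.0]
    n_boundary = len(all_eqs) - len(eqs)
    if len(eqs) < 4:
        raise ValueError(f"need >= 4 interior conditions, got {len(eqs)}")
    A = np.array([e.protocol.A_i for e in eqs])
    if A.max() / A.min() < 7.0 - 1e-9:
        raise ValueError("conditions must span at least ~a decade (7x) in A_i")
    N_eq = np.array([e.N_R_eq for e in eqs])
    out = any(e.protocol.A_i < 4.0 * e.protocol.k_eff(params) for e in eqs)
    slope, intercept = np.polyfit(A, N_eq, 1)
    resid = np.abs(slope * A + intercept - N_eq) / np.abs(N_eq)
    return ScalingFit(float(slope), float(intercept), float(resid.max()),
                      len(eqs), out, n_boundary)


def oscillation_scan(params: ModelParams, protocol: PassageProtocol,
                     A_values: Sequence[float]):
    """Stability multiplier and limit-cycle amplitude along a dose scan.

    ``A_values`` must be sorted in descending order and all exceed the
    MIC.  For each dose the fixed point and its multiplier λ come from
    :func:`find_equilibrium`; the amplitude is the max−min of the last
    20 iterates of a 200-iterate map orbit started at ``f* + 0.01``
    (zero at a stable fixed point, positive on a limit cycle).  Boundary
    attractors are reported with amplitude 0.
    """
    A_values = list(A_values)
    if any(a <= params.MIC for a in A_values):
        raise ValueError("all scanned doses must exceed the MIC")
    if A_values != sorted(A_values, reverse=True):
        raise ValueError("A_values must be sorted in descending order")
    import pandas as pd

    rows = []
    f_prev: float | None = None
    for A in A_values:
        proto = protocol.replace(A_i=A)
        guess = f_prev
        eq = find_equilibrium(params, proto, f_init=guess)
        amp = 0.0
        if eq.interior:
            f_prev = eq.f_star
            f = min(eq.f_star + 0.01, 1.0 - 1e-6)
            orbit = []
            for _ in range(ORBIT_LENGTH):
                f = step_map(f, params, proto)
                orbit.append(f)
            tail = orbit[-ORBIT_TAIL:]
            amp = max(tail) - min(tail)
            if abs(eq.lam) < 1.0:
                amp = 0.0 if amp < 1e-6 else amp
        rows.append({"A_ug_ml": A, "f_star": eq.f_star, "lam": eq.lam,
                     "amplitude": amp,
                     "classification": eq.classification})
    return pd.DataFrame(rows)


@dataclass
class SaturationProfile:
    """Time to reach saturation as a function of the initial fraction."""

    f: np.ndarray
    t_sat: np.ndarray            # NaN where saturation is not reached
    f_min: float | None          # argmin over reached conditions
    t_min: float | None


def saturation_time_profile(params: ModelParams, protocol: PassageProtocol,
                            f_grid: Sequence[float]) -> SaturationProfile:
    """Saturation time per initial resistant fraction, with its argmin.

    The model predicts the fastest-saturating composition is interior:
    more resistant cells clear the antibiotic sooner, but a fully
    resistant culture forfeits the sensitive strain's faster growth.
    Grid values must lie in (0, 1]; conditions that never saturate are
    reported as NaN and excluded from the argmin.
    """
    grid = np.asarray(f_grid, float)
    if np.any((grid <= 0.0) | (grid > 1.0)):
        raise ValueError("f_grid values must lie in (0,1]")
    N_i = protocol.inoculum(params)
    t_sat = np.full(len(grid), np.nan)
    for i, f in enumerate(grid):
        day = simulate_day(
            CultureState(0.0, f * N_i, (1.0 - f) * N_i, protocol.A_i),
            params, protocol)
        if day.t_sat is not None:
            t_sat[i] = day.t_sat
    if np.all(np.isnan(t_sat)):
        return SaturationProfile(grid, t_sat, None, None)
    i_min = int(np.nanargmin(t_sat))
    return SaturationProfile(grid, t_sat, float(grid[i_min]),
                             float(t_sat[i_min]))
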