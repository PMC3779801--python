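"""Day-to-day dynamics: difference-equation maps, cobwebbing, equilibria.

Iterating :func:`coopres.day.simulate_day` over daily dilution cycles
turns the within-day model into a one-dimensional map ``f_{n+1} = g(f_n)``
for the resistant fraction.  Interior fixed points of ``g`` are the
coexistence equilibria; the map derivative at the fixed point (the
stability multiplier λ) classifies the approach as monotone (0 ≤ λ < 1),
oscillatory (−1 < λ < 0) or unstable (|λ| ≥ 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .day import CultureState, simulate_day
from .params import ModelParams, PassageProtocol

__all__ = [
    "DifferenceMap",
    "EquilibriumResult",
    "Timecourse",
    "step_map",
    "run_timecourse",
    "build_difference_map",
    "find_equilibrium",
    "cobweb_path",
    "default_f_grid",
]

#: density floor (cells/µl) below which a deterministic lineage is
#: treated as extinct in multi-day runs
EXTINCTION_FLOOR = 1e-6

_LAM_STEP = 1e-4  # central finite-difference step for the multiplier


def step_map(f: float, params: ModelParams, protocol: PassageProtocol) -> float:
    """One application of the daily difference equation.

    Inoculates ``(f·N_i, (1−f)·N_i)`` into fresh medium at the protocol's
    antibiotic dose and returns the resistant fraction after ``T_day``.
    The endpoints are absorbing: ``g(0)=0`` and ``g(1)=1`` exactly.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"f must be in [0,1], got {f}")
    N_i = protocol.inoculum(params)
    initial = CultureState(0.0, f * N_i, (1.0 - f) * N_i, protocol.A_i)
    return simulate_day(initial, params, protocol).f_final


@dataclass
class Timecourse:
    """Daily resistant fractions from a multi-day passage experiment."""

    fractions: np.ndarray       # f after each day, length <= n_days
    extinct: bool = False       # True if the culture died out

    def __len__(self) -> int:
        return len(self.fractions)


def run_timecourse(f0: float, n_days: int, params: ModelParams,
                   protocol: PassageProtocol) -> Timecourse:
    """Iterate daily cycles with ``D``-fold dilution between days.

    Day 1 starts from the protocol inoculum at fraction ``f0``; each
    following day inoculates the previous day's final densities diluted
    by ``D`` (antibiotic reset to ``A_i``, residual carry-over neglected).
    Returns the resistant fraction measured at the end of each day.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if not 0.0 <= f0 <= 1.0:
        raise ValueError(f"f0 must be in [0,1], got {f0}")
    N_i = protocol.inoculum(params)
    N_R, N_S = f0 * N_i, (1.0 - f0) * N_i
    out: list[float] = []
    for _ in range(n_days):
        if N_R + N_S < EXTINCTION_FLOOR:
            return Timecourse(np.asarray(out), extinct=True)
        day = simulate_day(CultureState(0.0, N_R, N_S, protocol.A_i),
                           params, protocol)
        out.append(day.f_final)
        N_R = day.final_state.N_R / protocol.D
        N_S = day.final_state.N_S / protocol.D
    return Timecourse(np.asarray(out))


def default_f_grid(n: int = 24, lo: float = 1e-3, hi: float = 0.999) -> np.ndarray:
    """Logit-spaced grid of initial fractions strictly inside (0,1)."""
    return expit(np.linspace(logit(lo), logit(hi), n))


@dataclass
class DifferenceMap:
    """Sampled difference equation for one condition."""

    params: ModelParams
    protocol: PassageProtocol
    points: np.ndarray          # shape (n, 2): columns f_initial, f_final
    errors: list[tuple[float, str]] = field(default_factory=list)

    @property
    def f_initial(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def f_final(self) -> np.ndarray:
        return self.points[:, 1]

    def to_frame(self, condition_id: str = "c0"):
        import pandas as pd

        return pd.DataFrame({
            "condition_id": condition_id,
            "A_ug_ml": self.protocol.A_i,
            "inhibitor_ng_ml": self.protocol.I,
            "dilution": self.protocol.D,
            "f_initial": self.f_initial,
            "f_final": self.f_final,
        })


def build_difference_map(params: ModelParams, protocol: PassageProtocol,
                         f_grid: Sequence[float] | None = None) -> DifferenceMap:
    """Evaluate the daily map on a grid of initial fractions.

    The default grid mirrors a 24-point experimental design, logit-spaced
    between 1e-3 and 0.999.  Per-point failures are recorded (with the
    offending fraction) rather than aborting the whole map.
    """
    grid = default_f_grid() if f_grid is None else np.asarray(f_grid, float)
    if np.any((grid <= 0.0) | (grid >= 1.0)):
        raise ValueError("f_grid values must lie strictly inside (0,1)")
    pts = np.empty((len(grid), 2))
    errors: list[tuple[float, str]] = []
    for i, f in enumerate(grid):
        pts[i, 0] = f
        try:
            pts[i, 1] = step_map(float(f), params, protocol)
        except Exception as exc:  # recorded, not fatal
            pts[i, 1] = np.nan
            errors.append((float(f), repr(exc)))
    return DifferenceMap(params, protocol, pts, errors)


@dataclass
class EquilibriumResult:
    """Fixed point of the daily map for one condition.

    ``f_star`` is the primary equilibrium fraction (0 or 1 for a boundary
    attractor), ``N_R_eq = f_star · N_i`` the equilibrium inoculum density
    of resistant cells, ``lam`` the stability multiplier g′(f*), and
    ``classification`` one of ``stable-monotone``, ``stable-oscillatory``,
    ``unstable`` or ``boundary``.
    """

    f_star: float
    N_R_eq: float
    lam: float
    classification: str
    protocol: PassageProtocol
    all_roots: tuple[float, ...] = ()

    @property
    def interior(self) -> bool:
        return self.classification != "boundary"

    @property
    def stable(self) -> bool:
        return abs(self.lam) < 1.0

    def to_dict(self) -> dict:
        return {
            "f_star": self.f_star,
            "N_R_eq_per_ul": self.N_R_eq,
            "lam": self.lam,
            "classification": self.classification,
            "A_ug_ml": self.protocol.A_i,
            "inhibitor_ng_ml": self.protocol.I,
            "dilution": self.protocol.D,
        }


def _classify(lam: float) -> str:
    if abs(lam) >= 1.0:
        return "unstable"
    return "stable-oscillatory" if lam < 0.0 else "stable-monotone"


def find_equilibrium(params: ModelParams, protocol: PassageProtocol,
                     n_scan: int = 200, f_init: float | None = None,
                     xtol: float = 1e-9, quick: bool = False) -> EquilibriumResult:
    """Locate the interior fixed point of the daily map, with stability.

    A coarse grid scan brackets sign changes of ``g(f) − f``; each bracket
    is refined by Brent's method to ``|g(f*) − f*| < 1e-6``.  When
    ``f_init`` is given, a bracket is first grown around it, which skips
    the scan in the common single-root case (used heavily by the fitter).
    If no interior crossing exists the boundary attractor (0 or 1) is
    reported instead of failing.  If several interior roots are found,
    all are reported and the stable one with the widest bracket gap is
    flagged primary.

    ``quick=True`` (used in fitting inner loops) trusts the bracket
    expansion: when it reaches the domain edges without a sign change the
    boundary attractor is reported without falling back to the grid
    scan, and the stability multiplier is not computed.  Correct for
    maps with at most one interior crossing, which is the regime of this
    model.
    """
    g_minus_f = lambda f: step_map(f, params, protocol) - f
    lo, hi = 1e-4, 1.0 - 1e-4
    roots: list[float] = []

    if f_init is not None and lo < f_init < hi:
        # grow a bracket around the guess: g-f is >0 below a stable
        # interior root and <0 above it
        a = b = float(np.clip(f_init, lo, hi))
        ha = hb = g_minus_f(a)
        if ha == 0.0:  # the guess is already the fixed point
            roots = [a]
        width = 0.05
        while not roots and ha < 0.0 and a > lo:
            a = max(a - width, lo)
            ha = g_minus_f(a)
            width *= 2.0
        width = 0.05
        while not roots and hb > 0.0 and b < hi:
            b = min(b + width, hi)
            hb = g_minus_f(b)
            width *= 2.0
        if roots:
            pass
        elif ha > 0.0 > hb:
            roots = [brentq(g_minus_f, a, b, xtol=xtol)]
        elif quick:
            if ha <= 0.0 < hb:  # inverted ordering: unstable crossing only
                roots = [brentq(lambda f: -g_minus_f(f), a, b, xtol=xtol)]
            else:
                f_b = 1.0 if hb > 0.0 else 0.0
                N_i = protocol.inoculum(params)
                return EquilibriumResult(f_b, f_b * N_i, 0.0, "boundary",
                                         protocol)

    if not roots:
        fs = np.linspace(lo, hi, n_scan)
        hv = np.array([g_minus_f(f) for f in fs])
        for i in range(len(fs) - 1):
            if hv[i] == 0.0:
                roots.append(float(fs[i]))
            elif hv[i] * hv[i + 1] < 0.0:
                roots.append(brentq(g_minus_f, fs[i], fs[i + 1], xtol=xtol))
        if not roots:
            # boundary attractor: the map lies entirely on one side
            f_b = 1.0 if hv[len(hv) // 2] > 0.0 else 0.0
            N_i = protocol.inoculum(params)
            return EquilibriumResult(f_b, f_b * N_i, 0.0, "boundary",
                                     protocol)

    lams = [_map_derivative(r, params, protocol) for r in roots]
    if len(roots) == 1:
        primary = 0
    else:
        # widest gap between neighbouring roots/edges, preferring stable
        edges = [lo] + sorted(roots) + [hi]
        gaps = {}
        for i, r in enumerate(sorted(roots)):
            gaps[r] = edges[i + 2] - edges[i]
        order = sorted(range(len(roots)),
                       key=lambda i: (abs(lams[i]) >= 1.0, -gaps[roots[i]]))
        primary = order[0]
    f_star = roots[primary]
    lam = lams[primary]
    N_i = protocol.inoculum(params)
    return EquilibriumResult(f_star, f_star * N_i, lam, _classify(lam),
                             protocol, tuple(roots))


def _map_derivative(f: float, params: ModelParams,
                    protocol: PassageProtocol) -> float:
    h = _LAM_STEP
    a = max(f - h, 0.0)
    b = min(f + h, 1.0)
    return (step_map(b, params, protocol)
            - step_map(a, params, protocol)) / (b - a)


def cobweb_path(f0: float, n: int,
                step: Callable[[float], float] | DifferenceMap) -> np.ndarray:
    """Cobweb iteration points for graphical map analysis.

    Returns an array of (x, y) vertices alternating vertical moves to the
    map curve and horizontal moves to the diagonal:
    ``(f0,f0) → (f0,f1) → (f1,f1) → (f1,f2) → …`` for ``n`` applications
    of the map.  ``step`` may be a callable or a sampled
    :class:`DifferenceMap` (interpolated linearly).
    """
    if not 0.0 < f0 < 1.0:
        raise ValueError(f"f0 must be in (0,1), got {f0}")
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return np.empty((0, 2))
    if isinstance(step, DifferenceMap):
        m = step
        order = np.argsort(m.f_initial)
        step_fn = lambda f: float(np.interp(f, m.f_initial[order],
                                            m.f_final[order]))
    else:
        step_fn = step
    pts = [(f0, f0)]
    f = f0
    for _ in range(n):
        f_next = step_fn(f)
        pts.append((f, f_next))
        pts.append((f_next, f_next))
        f = f_next
    return np.asarray(pts)
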