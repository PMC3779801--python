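"""Estimation of (MIC, V_max, K_M) and K_I from equilibrium fractions.

The observables are equilibrium resistant fractions measured across
antibiotic doses, dilution factors and (for the inhibitor fit) inhibitor
concentrations.  The objective is unweighted least squares on fractions
(1/se² weighting available behind a flag); model equilibria come from the
numeric fixed-point finder, not the closed-form approximation, to avoid
approximation bias.  The closed form is used only to seed the optimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .analytics import analytic_equilibrium
from .params import ModelParams, PassageProtocol
from .passage import find_equilibrium

__all__ = ["ObservationTable", "FitResult", "loss", "fit_core", "fit_ki",
           "CORE_BOUNDS", "KI_BOUNDS"]

OBS_COLUMNS = ["condition_id", "A_ug_ml", "inhibitor_ng_ml", "dilution",
               "N_i_per_ul", "f_eq_obs", "se", "n_reps"]

#: fit bounds, roughly a decade-plus around the defaults
CORE_BOUNDS = {
    "MIC": (0.1, 10.0),          # µg/ml
    "V_max_raw": (1e4, 1e8),     # molecules/(CFU·s)
    "K_M": (0.5, 100.0),         # µg/ml
}
KI_BOUNDS = (0.1, 1000.0)        # ng/ml

# coarser fixed-point scan used inside the objective; the bracket fast
# path almost always succeeds, the scan is a fallback
_LOSS_N_SCAN = 64


class ObservationTable:
    """Equilibrium-fraction observations, one row per condition.

    Wraps a DataFrame with columns ``condition_id, A_ug_ml,
    inhibitor_ng_ml, dilution, N_i_per_ul, f_eq_obs, se, n_reps``.
    Fractions must lie strictly inside (0, 1); standard errors are
    non-negative.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in OBS_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing observation columns: {missing}")
        extra = [c for c in df.columns if c not in OBS_COLUMNS]
        if extra:
            raise ValueError(f"unknown observation columns: {extra}")
        df = df.reset_index(drop=True)
        bad = df.index[(df["f_eq_obs"] <= 0.0) | (df["f_eq_obs"] >= 1.0)]
        if len(bad):
            raise ValueError(
                f"f_eq_obs outside (0,1) at rows {list(bad)} "
                f"(file line = row + 2)")
        if (df["se"] < 0).any():
            raise ValueError("se must be >= 0")
        df = df[OBS_COLUMNS].copy()
        for col in ("A_ug_ml", "inhibitor_ng_ml", "dilution", "N_i_per_ul",
                    "f_eq_obs", "se"):
            df[col] = df[col].astype(float)
        df["n_reps"] = df["n_reps"].astype(int)
        df["condition_id"] = df["condition_id"].astype(str)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def protocols(self, T_day: float = 23.0) -> Iterator[tuple[str, PassageProtocol, float, float]]:
        """Yield (condition_id, protocol, f_obs, se) per row."""
        for row in self.df.itertuples(index=False):
            proto = PassageProtocol(A_i=row.A_ug_ml, I=row.inhibitor_ng_ml,
                                    D=row.dilution, T_day=T_day,
                                    N_i=row.N_i_per_ul)
            yield row.condition_id, proto, row.f_eq_obs, row.se


@dataclass
class FitResult:
    """Outcome of a parameter fit."""

    estimates: dict[str, float]
    loss: float
    n_evals: int
    converged: bool
    message: str = ""
    starts: list[dict] = field(default_factory=list)

    UNIT_KEYS = {
        "MIC": "MIC_ug_ml",
        "V_max_raw": "V_max_raw_molecules_per_cfu_s",
        "K_M": "K_M_ug_ml",
        "K_I": "K_I_ng_ml",
    }

    def to_dict(self) -> dict:
        out = {self.UNIT_KEYS.get(k, k): v for k, v in self.estimates.items()}
        out["loss"] = self.loss
        out["n_evals"] = self.n_evals
        out["converged"] = self.converged
        return out


def _model_equilibrium(params: ModelParams, proto: PassageProtocol,
                       f_guess: float | None) -> float:
    """Model equilibrium fraction for one condition; boundary -> 0 or 1."""
    if f_guess is None:
        try:
            f_guess = analytic_equilibrium(params, proto)
        except ValueError:
            f_guess = None
        else:
            f_guess = min(max(f_guess, 1e-3), 1.0 - 1e-3)
    if f_guess is None:
        f_guess = 0.5
    eq = find_equilibrium(params, proto, n_scan=_LOSS_N_SCAN,
                          f_init=f_guess, quick=True)
    return eq.f_star


def loss(theta: Mapping[str, float], obs: ObservationTable,
         fixed: ModelParams, weighted: bool = False,
         _cache: dict | None = None) -> float:
    """Sum of squared residuals between model and observed equilibria.

    ``theta`` overrides fields of ``fixed`` (e.g. MIC, V_max_raw, K_M,
    K_I).  Conditions without an interior equilibrium contribute their
    boundary attractor (0 or 1) as the model value.
    """
    params = fixed.replace(**dict(theta))
    total = 0.0
    for cid, proto, f_obs, se in obs.protocols():
        guess = _cache.get(cid) if _cache is not None else None
        f_model = _model_equilibrium(params, proto, guess)
        if _cache is not None and 0.0 < f_model < 1.0:
            _cache[cid] = f_model
        w = 1.0 / se**2 if (weighted and se > 0) else 1.0
        total += w * (f_model - f_obs) ** 2
    return total


def _core_pack(theta: Mapping[str, float]) -> np.ndarray:
    return np.array([theta["MIC"], math.log10(theta["V_max_raw"]),
                     math.log10(theta["K_M"])])


def _core_unpack(x: np.ndarray) -> dict[str, float]:
    return {"MIC": float(x[0]), "V_max_raw": float(10.0 ** x[1]),
            "K_M": float(10.0 ** x[2])}


_CORE_X_BOUNDS = [
    CORE_BOUNDS["MIC"],
    (math.log10(CORE_BOUNDS["V_max_raw"][0]), math.log10(CORE_BOUNDS["V_max_raw"][1])),
    (math.log10(CORE_BOUNDS["K_M"][0]), math.log10(CORE_BOUNDS["K_M"][1])),
]


def _analytic_start(obs: ObservationTable, fixed: ModelParams) -> dict[str, float]:
    """Cheap starting point: least squares on the closed-form equilibrium."""

    def aloss(x: np.ndarray) -> float:
        params = fixed.replace(**_core_unpack(x))
        s = 0.0
        for _, proto, f_obs, _ in obs.protocols():
            try:
                f_model = analytic_equilibrium(params, proto)
            except ValueError:
                f_model = 0.0
            s += (f_model - f_obs) ** 2
        return s

    res = minimize(aloss, _core_pack({"MIC": 1.0, "V_max_raw": 1e6, "K_M": 5.0}),
                   method="Nelder-Mead", bounds=_CORE_X_BOUNDS,
                   options={"maxfev": 600, "xatol": 1e-4, "fatol": 1e-12})
    return _core_unpack(res.x)


def fit_core(obs: ObservationTable, fixed: ModelParams | None = None,
             n_starts: int = 5, seed: int = 0,
             weighted: bool = False) -> FitResult:
    """Fit (MIC, V_max_raw, K_M) to observed equilibrium fractions.

    Growth/death/lag parameters stay fixed at their measured values.
    Requires at least 6 conditions spanning at least 2 dilution factors.
    Bounded derivative-free (Nelder–Mead) minimization over linear MIC
    and log10-parameterized (V_max_raw, K_M), multi-started from the
    closed-form heuristic plus seeded random points; the best start wins.
    Bit-reproducible for a given ``seed``.
    """
    if fixed is None:
        fixed = ModelParams()
    if len(obs) < 6:
        raise ValueError(f"need >= 6 conditions, got {len(obs)}")
    if obs.df["dilution"].nunique() < 2:
        raise ValueError("need >= 2 distinct dilution factors")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")

    n_evals = 0

    def objective(x: np.ndarray, cache: dict) -> float:
        nonlocal n_evals
        n_evals += 1
        return loss(_core_unpack(x), obs, fixed, weighted=weighted,
                    _cache=cache)

    rng = np.random.default_rng(seed)
    starts = [_core_pack(_analytic_start(obs, fixed))]
    lo = np.array([b[0] for b in _CORE_X_BOUNDS])
    hi = np.array([b[1] for b in _CORE_X_BOUNDS])
    for _ in range(n_starts - 1):
        starts.append(lo + rng.random(3) * (hi - lo))

    best = None
    records = []
    for x0 in starts:
        cache: dict = {}
        res = minimize(objective, x0, args=(cache,), method="Nelder-Mead",
                       bounds=_CORE_X_BOUNDS,
                       options={"maxfev": 400, "xatol": 1e-6,
                                "fatol": 1e-14, "adaptive": True})
        records.append({"x0": list(x0), "loss": float(res.fun),
                        "success": bool(res.success)})
        if best is None or res.fun < best.fun:
            best = res
    converged = any(r["success"] for r in records)
    return FitResult(estimates=_core_unpack(best.x), loss=float(best.fun),
                     n_evals=n_evals, converged=converged,
                     message=str(best.message), starts=records)


def fit_ki(obs: ObservationTable, fixed: ModelParams) -> FitResult:
    """Fit the inhibitor dissociation constant K_I, all else held fixed.

    Requires at least 3 inhibitor levels including 0; a table whose
    fractions do not respond to the inhibitor drives the estimate to the
    upper bound, which is flagged as non-converged.
    """
    levels = sorted(obs.df["inhibitor_ng_ml"].unique())
    if len(levels) < 3:
        raise ValueError(f"need >= 3 inhibitor levels, got {len(levels)}")
    if 0.0 not in levels:
        raise ValueError("inhibitor series must include I=0")
    if (obs.df["f_eq_obs"] >= 1.0 - 1e-9).all():
        raise ValueError("all observations fully resistant: K_I unidentifiable")

    n_evals = 0
    cache: dict = {}

    def objective(log_ki: float) -> float:
        nonlocal n_evals
        n_evals += 1
        return loss({"K_I": 10.0 ** log_ki}, obs, fixed, _cache=cache)

    lo, hi = math.log10(KI_BOUNDS[0]), math.log10(KI_BOUNDS[1])
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    ki = float(10.0 ** res.x)
    at_upper = ki > KI_BOUNDS[1] * 10 ** (-3 * 1e-4)  # within ~0.07% of bound
    msg = "K_I ran to upper bound (no inhibitor effect?)" if at_upper else ""
    return FitResult(estimates={"K_I": ki}, loss=float(res.fun),
                     n_evals=n_evals, converged=bool(res.success) and not at_upper,
                     message=msg)
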