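"""Synthetic datasets with the statistical structure of the measurements.

Real equilibrium fractions were measured by flow cytometry on replicate
serial-dilution cultures.  The generator reproduces that design: for each
condition (dose, inhibitor, dilution) it finds the model equilibrium
under a per-replicate-day perturbation of the saturation density
(a multiplicative lognormal "media/day" effect), then corrupts the
fraction with binomial counting noise (``k ~ Binomial(n_events, f)``,
the event count of a cytometry sample).  Datasets are byte-reproducible
from (design, truth parameters, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .params import ModelParams, PassageProtocol
from .passage import find_equilibrium, step_map
from .fitting import ObservationTable, OBS_COLUMNS

__all__ = [
    "NoiseModel",
    "DesignPoint",
    "SyntheticDataset",
    "measure_fraction",
    "gen_equilibrium_dataset",
    "gen_map_dataset",
    "preset_design",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement and replicate noise settings.

    ``n_events`` — cytometry events counted per sample (binomial noise
    sd ≈ sqrt(f(1−f)/n_events), ~0.005 at f=0.5 for 1e4 events), or
    ``None`` to disable counting noise entirely (fractions reported
    exactly); ``day_effect_sd`` — lognormal sd applied multiplicatively
    to the saturation density per replicate-day; ``seed`` — RNG seed
    (identical seed means identical dataset).
    """

    n_events: int | None = 10_000
    day_effect_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events is not None and self.n_events < 1:
            raise ValueError("n_events must be >= 1")
        if self.day_effect_sd < 0:
            raise ValueError("day_effect_sd must be >= 0")

    @property
    def exact(self) -> bool:
        return self.day_effect_sd == 0.0 and self.n_events is None


@dataclass(frozen=True)
class DesignPoint:
    """One experimental condition of a synthetic design."""

    A_i: float           # µg/ml
    I: float = 0.0       # ng/ml
    D: float = 100.0


@dataclass
class SyntheticDataset:
    """Generated observations plus full provenance.

    ``observations`` is an :class:`ObservationTable` (equilibrium
    designs) and/or ``map_points`` a DataFrame of (f_initial, f_final)
    samples; ``manifest`` records the truth parameters, design and seed
    needed to regenerate the data exactly.
    """

    design: list[DesignPoint]
    truth: ModelParams
    noise: NoiseModel
    observations: ObservationTable | None = None
    map_points: pd.DataFrame | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def manifest(self) -> dict:
        return {
            "truth": self.truth.to_dict(),
            "noise": dataclasses.asdict(self.noise),
            "design": [dataclasses.asdict(d) for d in self.design],
        }


def measure_fraction(f_true: float, noise: NoiseModel,
                     rng: np.random.Generator) -> float:
    """One flow-cytometry fraction readout: Binomial(n_events, f)/n_events.

    With counting noise disabled (``n_events=None``) the true fraction is
    returned unchanged.
    """
    if not 0.0 <= f_true <= 1.0:
        raise ValueError(f"f_true must be in [0,1], got {f_true}")
    if noise.n_events is None:
        return float(f_true)
    return float(rng.binomial(noise.n_events, f_true)) / noise.n_events


def preset_design(name: str) -> list[DesignPoint]:
    """Named designs emulating the study's figures.

    ``"fig3"`` — dose–dilution grid (5 ampicillin doses × 4 dilution
    factors); the exact experimental condition set is only shown
    graphically, so this is an approximation.  ``"fig4"`` — tazobactam
    series at 20 µg/ml ampicillin, 100× dilution.
    """
    if name == "fig3":
        return [DesignPoint(A_i=a, D=d)
                for a in (12.5, 25.0, 50.0, 100.0, 200.0)
                for d in (100.0, 200.0, 400.0, 800.0)]
    if name == "fig4":
        return [DesignPoint(A_i=20.0, I=i, D=100.0)
                for i in (0.0, 50.0, 100.0, 200.0, 400.0, 700.0, 1000.0)]
    raise ValueError(f"unknown design preset: {name!r}")


def _condition_protocol(point: DesignPoint, params: ModelParams,
                        T_day: float) -> PassageProtocol:
    return PassageProtocol(A_i=point.A_i, I=point.I, D=point.D, T_day=T_day)


def gen_equilibrium_dataset(truth: ModelParams,
                            design: Sequence[DesignPoint],
                            noise: NoiseModel,
                            n_reps: int = 3,
                            T_day: float = 23.0) -> SyntheticDataset:
    """Noisy equilibrium fractions for a dose/inhibitor/dilution design.

    Per condition and replicate: perturb the saturation density by the
    day effect, locate the model equilibrium, and apply counting noise;
    replicates are aggregated into mean and standard error (n=3 by
    default).  Conditions whose attractor is a boundary (fully sensitive
    or fully resistant) are flagged and reported with fractions clipped
    just inside (0,1).
    """
    rng = np.random.default_rng(noise.seed)
    rows = []
    flags: list[str] = []
    # clip strictly inside (0,1); 1e-9 survives 9-significant-digit export
    eps = 1e-9 if noise.n_events is None else 1.0 / (4.0 * noise.n_events)
    f_prev: float | None = None
    for k, point in enumerate(design):
        obs_reps = []
        boundary = False
        for _ in range(n_reps):
            if noise.day_effect_sd > 0:
                factor = float(np.exp(rng.normal(0.0, noise.day_effect_sd)))
            else:
                factor = 1.0
            params_r = truth.replace(N_sat=truth.N_sat * factor)
            proto_r = _condition_protocol(point, params_r, T_day)
            eq = find_equilibrium(params_r, proto_r, f_init=f_prev)
            if eq.interior:
                f_prev = eq.f_star
            else:
                boundary = True
            obs_reps.append(measure_fraction(eq.f_star, noise, rng))
        mean = float(np.mean(obs_reps))
        se = float(np.std(obs_reps, ddof=1) / np.sqrt(len(obs_reps))) \
            if len(obs_reps) > 1 else 0.0
        cid = f"c{k:02d}"
        if boundary:
            flags.append(f"{cid}: boundary attractor")
        rows.append({
            "condition_id": cid,
            "A_ug_ml": point.A_i,
            "inhibitor_ng_ml": point.I,
            "dilution": point.D,
            "N_i_per_ul": truth.N_sat / point.D,
            "f_eq_obs": float(np.clip(mean, eps, 1.0 - eps)),
            "se": se,
            "n_reps": len(obs_reps),
        })
    table = ObservationTable(pd.DataFrame(rows, columns=OBS_COLUMNS))
    return SyntheticDataset(list(design), truth, noise,
                            observations=table, flags=flags)


def gen_map_dataset(truth: ModelParams,
                    design: Sequence[DesignPoint],
                    noise: NoiseModel,
                    f_grid: Sequence[float] | None = None,
                    n_days: int = 3,
                    T_day: float = 23.0) -> SyntheticDataset:
    """Noisy (f_initial, f_final) difference-map points.

    24 initial fractions per condition by default, replicated over
    ``n_days`` independent days.  The realized inoculum fraction is drawn
    binomially around the target (mixing error) and drives the actual
    dynamics; the final fraction receives counting noise on top.
    """
    from .passage import default_f_grid

    grid = default_f_grid() if f_grid is None else np.asarray(f_grid, float)
    rng = np.random.default_rng(noise.seed)
    rows = []
    for k, point in enumerate(design):
        for day in range(n_days):
            if noise.day_effect_sd > 0:
                factor = float(np.exp(rng.normal(0.0, noise.day_effect_sd)))
            else:
                factor = 1.0
            params_r = truth.replace(N_sat=truth.N_sat * factor)
            proto_r = _condition_protocol(point, params_r, T_day)
            for f_target in grid:
                f_act = measure_fraction(float(f_target), noise, rng)
                f_final = step_map(f_act, params_r, proto_r)
                rows.append({
                    "condition_id": f"c{k:02d}",
                    "A_ug_ml": point.A_i,
                    "inhibitor_ng_ml": point.I,
                    "dilution": point.D,
                    "day": day,
                    "f_initial": f_act,
                    "f_final": measure_fraction(f_final, noise, rng),
                })
    return SyntheticDataset(list(design), truth, noise,
                            map_points=pd.DataFrame(rows))


def equilibrium_from_map(map_points: pd.DataFrame) -> float:
    """Diagonal-crossing estimate of the equilibrium from noisy map points.

    Sorts points by initial fraction, smooths by a small rolling median,
    and interpolates the crossing of ``f_final − f_initial`` through 0.
    """
    pts = map_points.sort_values("f_initial")
    x = pts["f_initial"].to_numpy(float)
    y = pts["f_final"].to_numpy(float) - x
    if len(x) >= 9:
        y = pd.Series(y).rolling(5, center=True, min_periods=1).median().to_numpy()
    sign = np.sign(y)
    crossings = np.where((sign[:-1] > 0) & (sign[1:] <= 0))[0]
    if len(crossings) == 0:
        return 1.0 if y.mean() > 0 else 0.0
    i = crossings[-1]
    x0, x1, y0, y1 = x[i], x[i + 1], y[i], y[i + 1]
    if y0 == y1:
        return float(0.5 * (x0 + x1))
    return float(x0 - y0 * (x1 - x0) / (y1 - y0))
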