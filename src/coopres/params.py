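"""Model parameters, passage protocol, and unit conventions.

Canonical units throughout the package: time in hours, cell density in
cells/µl (equivalently CFU/µl), antibiotic concentration in µg/ml, and
inhibitor concentration in ng/ml.  The only unit conversion in the
package happens in :func:`convert_vmax`, which maps a per-cell hydrolysis
rate quoted in molecules/(CFU·s) onto the concentration scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

from scipy.constants import Avogadro

__all__ = [
    "ModelParams",
    "PassageProtocol",
    "convert_vmax",
    "effective_km",
    "validate_params",
    "params_from_mapping",
    "protocol_from_mapping",
    "load_config",
]

#: Ampicillin free acid molar mass, g/mol.  Needed to connect a hydrolysis
#: rate in molecules per cell per second to a concentration in µg/ml;
#: configurable for other β-lactams.
AMPICILLIN_MW = 349.4

_MODES = ("bactericidal", "bacteriostatic")


def convert_vmax(v_raw: float, MW: float = AMPICILLIN_MW) -> float:
    """Convert a per-cell hydrolysis rate to concentration units.

    Parameters
    ----------
    v_raw : float
        Maximum hydrolysis rate per cell, molecules/(CFU·s).
    MW : float
        Molar mass of the antibiotic, g/mol.

    Returns
    -------
    float
        Rate in (µg/ml)/h per (cell/µl): with ``N_R`` resistant cells/µl
        the bulk degradation term is ``V_max * N_R * A / (K_eff + A)``
        in (µg/ml)/h.

    Notes
    -----
    One cell hydrolyses ``v_raw * 3600`` molecules/h, i.e.
    ``v_raw * 3600 / N_A`` mol/h or ``v_raw * 3600 * MW * 1e6 / N_A`` µg/h.
    A density of 1 cell/µl is 1000 cells/ml, hence the factor 1e9.
    """
    if v_raw < 0:
        raise ValueError(f"v_raw must be >= 0, got {v_raw}")
    if MW <= 0:
        raise ValueError(f"MW must be > 0, got {MW}")
    return v_raw * 3600.0 * MW * 1e9 / Avogadro


def effective_km(K_M: float, I: float, K_I: float) -> float:
    """Effective Michaelis constant under a competitive inhibitor.

    ``K_eff = K_M * (1 + I / K_I)`` — competitive binding of the inhibitor
    (e.g. tazobactam) to the β-lactamase raises the apparent Michaelis
    constant linearly with the inhibitor concentration.

    Parameters are in µg/ml (``K_M``) and ng/ml (``I``, ``K_I``).
    """
    if K_M <= 0:
        raise ValueError(f"K_M must be > 0, got {K_M}")
    if I < 0:
        raise ValueError(f"I must be >= 0, got {I}")
    if K_I <= 0:
        raise ValueError(f"K_I must be > 0, got {K_I}")
    return K_M * (1.0 + I / K_I)


@dataclass(frozen=True)
class ModelParams:
    """Kinetic parameters of the two-strain serial-dilution model.

    Defaults are the study organism's measured/fitted values: resistant
    growth 1.1/h, sensitive growth 1.15× that (cost of resistance
    ≈0.165/h), death above MIC 2.8/h, 1 h lag, fitted MIC 1.1 µg/ml
    (measured ≈2 µg/ml), per-cell hydrolysis 1e6 molecules/(CFU·s),
    effective K_M 6.7 µg/ml, tazobactam K_I 4.6 ng/ml, saturation
    density 1e7 cells/µl.
    """

    gamma_R: float = 1.1          # resistant growth rate, /h
    gamma_S: float = 1.1 * 1.15   # sensitive growth rate below MIC, /h
    gamma_D: float = 2.8          # sensitive death rate above MIC, /h
    t_lag: float = 1.0            # lag-phase duration, h
    MIC: float = 1.1              # MIC of sensitive cells, µg/ml (fitted)
    V_max_raw: float = 1e6        # hydrolysis rate, molecules/(CFU·s)
    K_M: float = 6.7              # effective Michaelis constant, µg/ml
    K_I: float = 4.6              # inhibitor dissociation constant, ng/ml
    N_sat: float = 1e7            # saturation density, cells/µl
    MW: float = AMPICILLIN_MW     # antibiotic molar mass, g/mol
    mode: str = "bactericidal"
    V_max: float = field(init=False)  # (µg/ml)/h per (cell/µl), derived

    #: MIC measured by a conventional growth assay (µg/ml); used only in
    #: fold-ratio bookkeeping, never in the dynamics.
    MEASURED_MIC = 2.0

    def __post_init__(self) -> None:
        for name in ("gamma_R", "gamma_S", "gamma_D", "t_lag", "MIC",
                     "V_max_raw", "K_M", "K_I", "N_sat", "MW"):
            v = getattr(self, name)
            if not (v >= 0):
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.gamma_S <= self.gamma_R:
            raise ValueError(
                "cost-of-resistance violation: gamma_S must exceed gamma_R "
                f"(got gamma_S={self.gamma_S}, gamma_R={self.gamma_R})")
        if self.MIC <= 0 or self.K_M <= 0 or self.K_I <= 0 or self.N_sat <= 0:
            raise ValueError("MIC, K_M, K_I and N_sat must be > 0")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        object.__setattr__(self, "V_max", convert_vmax(self.V_max_raw, self.MW))

    @property
    def cost(self) -> float:
        """Metabolic cost of carrying the resistance plasmid, /h."""
        return self.gamma_S - self.gamma_R

    @property
    def death_rate(self) -> float:
        """Net sensitive-cell rate above MIC: −γ_D if bactericidal, 0 if
        bacteriostatic (growth stall without killing)."""
        return self.gamma_D if self.mode == "bactericidal" else 0.0

    def replace(self, **changes: Any) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        changes.pop("V_max", None)
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        """Init-field mapping (derived V_max excluded, so the dict can be
        fed back through the config loader unchanged)."""
        d = dataclasses.asdict(self)
        d.pop("V_max")
        return d


@dataclass(frozen=True)
class PassageProtocol:
    """One serial-dilution condition.

    Every day the saturated culture is diluted ``D``-fold into fresh
    medium containing antibiotic at ``A_i`` µg/ml (and inhibitor at ``I``
    ng/ml) and grown for ``T_day`` hours.  ``N_i`` is the inoculum density
    on day 1; ``None`` means the equilibrated default ``N_sat / D``.
    """

    A_i: float = 100.0   # antibiotic each day, µg/ml
    I: float = 0.0       # inhibitor, ng/ml
    D: float = 100.0     # dilution factor, dimensionless
    T_day: float = 23.0  # cycle length, h
    N_i: float | None = None  # day-1 inoculum, cells/µl; None -> N_sat/D

    def __post_init__(self) -> None:
        if self.A_i < 0:
            raise ValueError(f"A_i must be >= 0, got {self.A_i}")
        if self.I < 0:
            raise ValueError(f"I must be >= 0, got {self.I}")
        if self.D <= 1:
            raise ValueError(f"D must be > 1, got {self.D}")
        if self.T_day <= 0:
            raise ValueError(f"T_day must be > 0, got {self.T_day}")
        if self.N_i is not None and self.N_i <= 0:
            raise ValueError(f"N_i must be > 0, got {self.N_i}")

    def inoculum(self, params: ModelParams) -> float:
        """Day-1 inoculum density, cells/µl."""
        n = self.N_i if self.N_i is not None else params.N_sat / self.D
        if n > params.N_sat:
            raise ValueError(f"N_i={n} exceeds N_sat={params.N_sat}")
        return n

    def k_eff(self, params: ModelParams) -> float:
        """Effective Michaelis constant for this condition, µg/ml."""
        return effective_km(params.K_M, self.I, params.K_I)

    def validate_against(self, params: ModelParams) -> None:
        if self.T_day <= params.t_lag:
            raise ValueError(
                f"T_day={self.T_day} must exceed t_lag={params.t_lag}")
        self.inoculum(params)

    def replace(self, **changes: Any) -> "PassageProtocol":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_params(**candidate: Any) -> ModelParams:
    """Build a :class:`ModelParams` from a partial mapping.

    Omitted fields take the documented defaults; unknown keys raise.
    """
    return params_from_mapping(candidate)


_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParams) if f.init}
_PROTO_FIELDS = {f.name for f in dataclasses.fields(PassageProtocol)}


def params_from_mapping(mapping: Mapping[str, Any]) -> ModelParams:
    unknown = set(mapping) - _PARAM_FIELDS
    if unknown:
        raise ValueError(f"unknown ModelParams keys: {sorted(unknown)}")
    return ModelParams(**dict(mapping))


def protocol_from_mapping(mapping: Mapping[str, Any]) -> PassageProtocol:
    unknown = set(mapping) - _PROTO_FIELDS
    if unknown:
        raise ValueError(f"unknown PassageProtocol keys: {sorted(unknown)}")
    return PassageProtocol(**dict(mapping))


def load_config(path) -> tuple[ModelParams, PassageProtocol]:
    """Read a flat YAML/JSON config into (params, protocol).

    Keys must be named exactly as the ModelParams / PassageProtocol
    fields; unknown keys are an error.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw)}")
    unknown = set(raw) - _PARAM_FIELDS - _PROTO_FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    params = params_from_mapping({k: v for k, v in raw.items() if k in _PARAM_FIELDS})
    proto = protocol_from_mapping({k: v for k, v in raw.items() if k in _PROTO_FIELDS})
    proto.validate_against(params)
    return params, proto
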