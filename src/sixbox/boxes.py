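"""Domain types and parameter defaults for the six-box ocean model.

The ocean is split into three columns (Atlantic, Southern, Pacific), each
with a surface and a deep box: SA/DA, SS/DS, SP/DP.  Surface boxes host
biological production and air-sea gas exchange; deep boxes store exported
carbon and nutrients.  All concentrations are carried per kilogram of
seawater (umol kg-1 for DIC, ALK, PO4, NO3; nmol kg-1 for total iron and
total ligand); tendencies assembled per cubic metre are converted with a
single reference density ``RHO_SW``.
"""

from __future__ import annotations

import dataclasses
import enum
from collections.abc import Mapping
from typing import Any

import numpy as np

# Physical bookkeeping constants.
RHO_SW = 1024.5  # reference seawater density, kg m-3 (kg <-> m3 conversion)
SECONDS_PER_DAY = 86400.0
DAYS_PER_YEAR = 360.0  # model year used to convert yearly fluxes
SECONDS_PER_YEAR = SECONDS_PER_DAY * DAYS_PER_YEAR
M_FE = 55.845  # molar mass of iron, g mol-1
SV = 1.0e6  # Sverdrup, m3 s-1

TRACERS = ("dic", "alk", "po4", "no3", "fe", "lig")
#: multiplicative factor taking the customary unit of each tracer to mol kg-1
TRACER_SCALE = {"dic": 1e-6, "alk": 1e-6, "po4": 1e-6, "no3": 1e-6,
                "fe": 1e-9, "lig": 1e-9}


class Box(enum.IntEnum):
    """Box indices in Table order: Atlantic, Southern, Pacific columns."""

    SA = 0
    DA = 1
    SS = 2
    DS = 3
    SP = 4
    DP = 5


BOX_NAMES = tuple(b.name for b in Box)
SURFACE = (Box.SA, Box.SS, Box.SP)
DEEP = (Box.DA, Box.DS, Box.DP)
#: deep box directly underlying each surface box
DEEP_UNDER = {Box.SA: Box.DA, Box.SS: Box.DS, Box.SP: Box.DP}

_COLUMN_DEPTH = 4000.0  # m, fixed total thickness of each column

_DEFAULT_DX = (17.0e6,) * 6
_DEFAULT_DY = (4.0e6, 4.0e6, 2.0e6, 2.0e6, 8.0e6, 8.0e6)
_DEFAULT_DZ = (100.0, 3900.0, 100.0, 3900.0, 100.0, 3900.0)


@dataclasses.dataclass(frozen=True)
class BoxGeometry:
    """Dimensions of a single box (all lengths in metres)."""

    box: Box
    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError(f"non-positive dimension for box {self.box.name}")

    @property
    def area(self) -> float:
        """Horizontal area, m2."""
        return self.dx * self.dy

    @property
    def volume(self) -> float:
        """Volume, m3."""
        return self.area * self.dz

    @property
    def is_surface(self) -> bool:
        return self.box in SURFACE


def default_geometry(dz_overrides: Mapping[str, float] | None = None) -> list[BoxGeometry]:
    """Return the six default boxes, optionally with altered thicknesses.

    ``dz_overrides`` maps box names to new thicknesses, e.g.
    ``{"SA": 2000.0, "DA": 2000.0}`` deepens the Atlantic surface/deep
    interface.  Every column must keep its total 4000 m thickness.
    """
    dz = list(_DEFAULT_DZ)
    if dz_overrides:
        for name, value in dz_overrides.items():
            if name not in BOX_NAMES:
                raise KeyError(f"unknown box name {name!r}")
            dz[Box[name]] = float(value)
    for s, d in DEEP_UNDER.items():
        if abs(dz[s] + dz[d] - _COLUMN_DEPTH) > 1e-9:
            raise ValueError(
                f"column {s.name}/{d.name} thickness {dz[s] + dz[d]} m != {_COLUMN_DEPTH} m"
            )
    return [BoxGeometry(Box(i), _DEFAULT_DX[i], _DEFAULT_DY[i], dz[i]) for i in range(6)]


def geometry_arrays(geom: list[BoxGeometry]) -> dict[str, np.ndarray]:
    """Volumes, areas and masses of a geometry as arrays indexed by box."""
    vol = np.array([g.volume for g in geom])
    area = np.array([g.area for g in geom])
    return {"volume": vol, "area": area, "mass": vol * RHO_SW}


# --- parameters -----------------------------------------------------------

_POSITIVE_DEFINITE = (
    "r_c", "r_n", "r_p", "r_fe", "k_p", "k_n", "k_fe", "k_i",
    "beta", "k_pis", "l_fixed", "atm_moles_per_atm", "rho_sw",
)


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Full parameter set.  Per-box tuples follow Box order (SA..DP)."""

    ligand_mode: str = "fixed"  # "fixed" | "dynamic"
    # circulation
    psi: float = 20.0          # Southern Ocean upwelling, Sv
    f_amoc: float = 1.0        # AMOC as a fraction of psi
    f_smoc: float = 0.55       # SMOC as a fraction of psi
    f_return: float = 0.35     # deep Pacific->Southern return, fraction of psi
    kappa: float = 0.0         # bidirectional mixing exchange, Sv
    # biology
    alpha_bio: float = 6.0     # maximum production, umol P m-3 day-1
    r_c: float = 106.0         # C:P
    r_n: float = 16.0          # N:P
    r_p: float = 1.0
    r_fe: float = 1.0e-3       # Fe:P
    k_p: float = 0.1           # umol P kg-1
    k_n: float = 1.6           # umol N kg-1
    k_fe: float = 0.1          # nmol Fe kg-1
    k_i: float = 30.0          # W m-2
    light_in_minimum: bool = True  # include light in the Liebig minimum
    irradiance: tuple[float, ...] = (150.0, 0.0, 50.0, 0.0, 150.0, 0.0)  # W m-2
    # iron
    s_fe: tuple[float, ...] = (0.300, 0.027, 0.003, 0.013, 0.03, 0.054)  # g Fe m-2 y-1
    fe_solubility: float = 2.5e-3   # dissolving fraction of external iron
    beta: float = 1.0e9        # ligand stability constant, (mol m-3)-1
    k_scav: float = 1.0e-7     # scavenging of free iron, s-1
    fe_free_cap: float | None = None  # optional solubility ceiling, nmol kg-1
    # ligands
    gamma_per_p: float = 0.0   # mol ligand per mol P of organic production
    lambda_surf: float = 0.0   # surface degradation rate, s-1
    delta_lambda: tuple[float, ...] = (1.0, 0.01, 1.0, 0.01, 1.0, 0.01)
    l_fixed: float = 2.0       # fixed-mode ligand concentration, nmol kg-1
    # carbon / gas exchange
    k_pis: float = 0.337       # piston velocity coefficient, cm hr-1 (m s-1)-2
    wind: tuple[float, ...] = (5.0, 0.0, 10.0, 0.0, 5.0, 0.0)  # m s-1
    f_open: tuple[float, ...] = (1.0, 0.0, 1.0, 0.0, 1.0, 0.0)
    theta: tuple[float, ...] = (20.0, 4.0, -1.0, -1.0, 20.0, 4.0)  # deg C
    salinity: tuple[float, ...] = (35.50, 35.50, 34.75, 34.75, 35.00, 35.00)
    pco2_init: float = 280.0   # uatm
    atm_moles_per_atm: float = 1.773e20  # mol of gas per atm of pCO2
    rho_sw: float = RHO_SW

    def __post_init__(self) -> None:
        if self.ligand_mode not in ("fixed", "dynamic"):
            raise ValueError(f"unknown ligand_mode {self.ligand_mode!r}")
        if self.psi < 0 or self.kappa < 0 or self.f_return < 0:
            raise ValueError("psi, kappa and f_return must be non-negative")
        for name in _POSITIVE_DEFINITE:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")
        if min(self.gamma_per_p, self.lambda_surf, self.k_scav,
               self.alpha_bio) < 0:
            raise ValueError("rates must be non-negative")
        for f in self.f_open:
            if not 0.0 <= f <= 1.0:
                raise ValueError("f_open entries must lie in [0, 1]")
        for name in ("irradiance", "s_fe", "delta_lambda", "wind", "f_open",
                     "theta", "salinity"):
            if len(getattr(self, name)) != 6:
                raise ValueError(f"{name} must have one entry per box")

    @property
    def gamma_over_lambda(self) -> float:
        """Ligand feedback strength gamma/lambda in seconds, per mol C."""
        if self.lambda_surf == 0.0:
            return 0.0
        return self.gamma_per_p / self.r_c / self.lambda_surf

    def replace(self, **changes: Any) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


_DYNAMIC_LIGAND = {
    "gamma_per_p": 0.0053,          # mol L (mol P)-1
    "lambda_surf": 1.0 / 8.796e7,   # s-1 (surface lifetime 8.796e7 s)
}


def default_params(ligand_mode: str = "fixed",
                   overrides: Mapping[str, Any] | None = None) -> ModelParams:
    """Build the default parameter set for one of the two ligand modes.

    ``fixed`` pins a uniform 2 nmol kg-1 ligand pool with no sources or
    sinks; ``dynamic`` activates ligand production proportional to organic
    matter cycling and first-order decay.  ``overrides`` may set any
    :class:`ModelParams` field, plus the convenience keys
    ``ligand_lifetime_scale`` (multiplies the surface ligand lifetime, e.g.
    1.25 for the slow-decay sensitivity case) and ``fe_input_scale`` (a
    ``{box name: factor}`` mapping scaling external iron input).
    """
    values: dict[str, Any] = {"ligand_mode": ligand_mode}
    if ligand_mode == "dynamic":
        values.update(_DYNAMIC_LIGAND)
    elif ligand_mode != "fixed":
        raise ValueError(f"unknown ligand_mode {ligand_mode!r}")

    overrides = dict(overrides or {})
    lifetime_scale = overrides.pop("ligand_lifetime_scale", None)
    fe_scale = overrides.pop("fe_input_scale", None)

    field_names = {f.name for f in dataclasses.fields(ModelParams)}
    unknown = set(overrides) - field_names
    if unknown:
        raise KeyError(f"unknown parameter override(s): {sorted(unknown)}")
    for name, value in overrides.items():
        values[name] = tuple(value) if isinstance(value, (list, np.ndarray)) else value

    params = ModelParams(**values)
    if lifetime_scale is not None:
        if lifetime_scale <= 0:
            raise ValueError("ligand_lifetime_scale must be positive")
        params = params.replace(lambda_surf=params.lambda_surf / float(lifetime_scale))
    if fe_scale is not None:
        s_fe = list(params.s_fe)
        for name, factor in dict(fe_scale).items():
            s_fe[Box[name]] *= float(factor)
        params = params.replace(s_fe=tuple(s_fe))
    return params


# --- state ----------------------------------------------------------------

_INIT = {
    "dic": (2100.0, 2400.0, 2100.0, 2400.0, 2100.0, 2400.0),
    "alk": (2350.0, 2400.0, 2300.0, 2400.0, 2300.0, 2400.0),
    "po4": (0.0, 2.0, 2.0, 2.0, 0.0, 2.5),
    "no3": (0.0, 30.0, 30.0, 30.0, 0.0, 36.0),
    "fe": (0.0,) * 6,
}


@dataclasses.dataclass
class OceanState:
    """Per-box tracer concentrations plus the atmospheric carbon reservoir.

    dic/alk/po4/no3 in umol kg-1, fe/lig in nmol kg-1; pco2_atm in uatm.
    ``atm_mode`` is ``"clamped"`` (pCO2 held constant, used for
    equilibration) or ``"prognostic"`` (atmospheric inventory evolves with
    the net air-sea flux).
    """

    dic: np.ndarray
    alk: np.ndarray
    po4: np.ndarray
    no3: np.ndarray
    fe: np.ndarray
    lig: np.ndarray
    pco2_atm: float = 280.0
    atm_mode: str = "clamped"

    def __post_init__(self) -> None:
        for name in TRACERS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (6,):
                raise ValueError(f"{name} must have shape (6,)")
            object.__setattr__(self, name, arr)
        if self.atm_mode not in ("clamped", "prognostic"):
            raise ValueError(f"unknown atm_mode {self.atm_mode!r}")
        self.validate()

    def validate(self) -> None:
        for name in TRACERS:
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite {name}")
            if np.any(arr < 0):
                raise ValueError(f"negative {name}")
        if not np.isfinite(self.pco2_atm) or self.pco2_atm < 0:
            raise ValueError("invalid atmospheric pCO2")

    def copy(self) -> "OceanState":
        return OceanState(*(getattr(self, t).copy() for t in TRACERS),
                          pco2_atm=self.pco2_atm, atm_mode=self.atm_mode)

    def tracer_matrix(self) -> np.ndarray:
        """Tracers as a (6 tracers, 6 boxes) array in mol kg-1."""
        return np.stack([getattr(self, t) * TRACER_SCALE[t] for t in TRACERS])

    @classmethod
    def from_tracer_matrix(cls, mat: np.ndarray, pco2_atm: float,
                           atm_mode: str) -> "OceanState":
        fields = [mat[i] / TRACER_SCALE[t] for i, t in enumerate(TRACERS)]
        return cls(*fields, pco2_atm=pco2_atm, atm_mode=atm_mode)

    def atm_carbon(self, params: ModelParams) -> float:
        """Atmospheric carbon inventory, mol C."""
        return self.pco2_atm * 1e-6 * params.atm_moles_per_atm


def initial_state(params: ModelParams) -> OceanState:
    """Tabulated initial tracer concentrations for a spin-up."""
    lig = np.full(6, params.l_fixed) if params.ligand_mode == "fixed" else np.zeros(6)
    return OceanState(
        dic=np.array(_INIT["dic"]), alk=np.array(_INIT["alk"]),
        po4=np.array(_INIT["po4"]), no3=np.array(_INIT["no3"]),
        fe=np.array(_INIT["fe"]), lig=lig,
        pco2_atm=params.pco2_init, atm_mode="clamped",
    )
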