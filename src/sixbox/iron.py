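"""Iron speciation, scavenging, external sources and the prognostic ligand pool.

Dissolved iron partitions instantaneously between a free phase and a
complex with a single aggregate organic ligand pool, governed by the
conditional stability constant beta.  Only the free fraction is scavenged
(first order); ligand-bound iron is protected but remains bioavailable.
External iron enters the surface boxes as a soluble fraction of dust or
sedimentary deposition and the deep boxes as an area-weighted hydrothermal
source.  In dynamic mode the ligand pool is produced in proportion to
organic phosphorus cycling (actively at the surface, passively during deep
remineralization) and decays first order, one hundred times slower in the
deep ocean.

Note on units: beta is a volumetric stability constant, (mol m-3)-1, which
together with the other tabulated rates yields the nmol kg-1 iron
concentrations the six-box steady states exhibit; per-kg mass action uses
beta * rho_sw.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .boxes import (DEEP_UNDER, M_FE, RHO_SW, SECONDS_PER_YEAR, SURFACE,
                    BoxGeometry, ModelParams, OceanState)

_SPECIATION_RTOL = 1e-10


@dataclasses.dataclass
class IronSpeciation:
    """Partitioning of total iron against the ligand pool (nmol kg-1)."""

    fe_total: np.ndarray
    ligand_total: np.ndarray
    fe_free: np.ndarray
    fe_ligand: np.ndarray
    ligand_free: np.ndarray

    def validate(self) -> None:
        scale = np.maximum(np.maximum(self.fe_total, self.ligand_total), 1e-30)
        if np.any(np.abs(self.fe_free + self.fe_ligand - self.fe_total)
                  > _SPECIATION_RTOL * scale):
            raise AssertionError("iron mass balance violated")
        if np.any(np.abs(self.ligand_free + self.fe_ligand - self.ligand_total)
                  > _SPECIATION_RTOL * scale):
            raise AssertionError("ligand mass balance violated")


def free_iron_molkg(fe_total, ligand_total, beta_kg):
    """Free iron from total iron and ligand (all mol kg-1).

    Positive root of ``beta*Fe'^2 + (beta*(LT - FeT) + 1)*Fe' - FeT = 0``
    in the cancellation-free form ``2*FeT / (q + sqrt(q^2 + 4*beta*FeT))``
    with ``q = beta*(LT - FeT) + 1``, stable even when beta*|LT-FeT| >> 1.
    """
    fe_total = np.asarray(fe_total, dtype=float)
    ligand_total = np.asarray(ligand_total, dtype=float)
    q = beta_kg * (ligand_total - fe_total) + 1.0
    disc = np.sqrt(q * q + 4.0 * beta_kg * fe_total)
    return 2.0 * fe_total / (q + disc)


def solve_speciation(fe_total, ligand_total, beta: float,
                     rho_sw: float = RHO_SW) -> IronSpeciation:
    """Equilibrium speciation for total iron and ligand in nmol kg-1.

    ``beta`` is the volumetric stability constant (mol m-3)-1.
    """
    fe_total = np.asarray(fe_total, dtype=float)
    ligand_total = np.asarray(ligand_total, dtype=float)
    if np.any(fe_total < 0) or np.any(ligand_total < 0):
        raise ValueError("negative concentrations")
    if beta <= 0:
        raise ValueError("beta must be positive")
    beta_kg = beta * rho_sw
    fe_free = free_iron_molkg(fe_total * 1e-9, ligand_total * 1e-9, beta_kg) * 1e9
    fe_free = np.minimum(fe_free, fe_total)
    # The complex from its own stable quadratic root (avoids cancellation in
    # FeT - Fe' when little iron is bound); use whichever species is smaller
    # directly and recover the other by difference.
    ft, lt = fe_total * 1e-9, ligand_total * 1e-9
    p = beta_kg * (ft + lt) + 1.0
    disc = np.sqrt(np.maximum(p * p - 4.0 * beta_kg ** 2 * ft * lt, 0.0))
    fel_direct = 2.0 * beta_kg * ft * lt / (p + disc) * 1e9
    fe_ligand = np.where(fe_free <= fel_direct, fe_total - fe_free, fel_direct)
    fe_free = np.where(fe_free <= fel_direct, fe_free, fe_total - fel_direct)
    spec = IronSpeciation(
        fe_total=fe_total, ligand_total=ligand_total, fe_free=fe_free,
        fe_ligand=fe_ligand, ligand_free=ligand_total - fe_ligand)
    spec.validate()
    return spec


def scavenging_tendency(speciation: IronSpeciation, k_scav: float,
                        fe_free_cap: float | None = None) -> np.ndarray:
    """Total-iron loss to scavenging, nmol kg-1 s-1 (non-positive).

    Only the free fraction is scavenged.  If ``fe_free_cap`` is set, free
    iron below the cap is treated as soluble and exempt (a crude
    solubility threshold); disabled by default.
    """
    fe_free = speciation.fe_free
    if fe_free_cap is not None:
        fe_free = np.maximum(fe_free - fe_free_cap, 0.0)
    return -k_scav * fe_free


def iron_sources(geom: list[BoxGeometry], params: ModelParams) -> np.ndarray:
    """External iron input per box, nmol Fe kg-1 s-1.

    Surface entries represent dust/sediment/river deposition, deep entries
    hydrothermal venting; all are scaled by the dissolving fraction
    ``fe_solubility`` and converted from g Fe m-2 yr-1 with a 360-day year.
    """
    area = np.array([g.area for g in geom])
    vol = np.array([g.volume for g in geom])
    s_fe = np.asarray(params.s_fe, dtype=float)
    mol_per_s = s_fe * params.fe_solubility * area / (M_FE * SECONDS_PER_YEAR)
    return mol_per_s / (vol * params.rho_sw) * 1e9


def ligand_tendencies(state: OceanState, j: np.ndarray, remin_p: np.ndarray,
                      params: ModelParams) -> np.ndarray:
    """Ligand source minus decay per box, nmol L kg-1 s-1.

    ``j`` is surface production (SA, SS, SP; umol P m-3 day-1) and
    ``remin_p`` the per-box remineralization rate (umol P kg-1 s-1,
    non-zero in deep boxes).  Fixed mode returns zeros: the pool is pinned.
    """
    from .boxes import SECONDS_PER_DAY

    if params.ligand_mode == "fixed":
        if params.gamma_per_p != 0.0 or params.lambda_surf != 0.0:
            raise ValueError("fixed ligand mode with non-zero ligand rates")
        return np.zeros(6)
    j = np.asarray(j, dtype=float)
    p_rate = np.asarray(remin_p, dtype=float).copy()  # umol P kg-1 s-1
    for n, s in enumerate(SURFACE):
        p_rate[s] = j[n] / params.rho_sw / SECONDS_PER_DAY
    production = params.gamma_per_p * p_rate * 1e3     # nmol L kg-1 s-1
    decay = params.lambda_surf * np.asarray(params.delta_lambda) * state.lig
    return production - decay
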