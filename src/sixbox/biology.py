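"""Biological production, export and remineralization.

Production in each surface box follows Michaelis-Menten saturation in
phosphate, nitrate, dissolved iron and light, combined with Liebig's law
of the minimum: the smallest of the four dimensionless factors scales the
maximum volumetric rate alpha_bio.  All organic matter produced in a
surface box is exported and remineralized in the directly underlying deep
box with fixed C:N:P:Fe = 106:16:1:1e-3 stoichiometry; alkalinity changes
only through the nitrate uptake/release (no carbonate counter-pump).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .boxes import (DEEP_UNDER, SURFACE, Box, BoxGeometry, ModelParams,
                    OceanState)

LIMITERS = ("P", "N", "Fe", "light")

#: relative tolerance for the export/remineralization closure audit
_CLOSURE_RTOL = 1e-10


def limitation_terms(po4, no3, fe, irradiance, params: ModelParams) -> np.ndarray:
    """The four saturation factors X/(X + k_X), stacked on a new first axis.

    Concentrations in their customary units (umol kg-1 for PO4/NO3,
    nmol kg-1 for Fe; irradiance in W m-2).  Each factor lies in [0, 1).
    """
    po4, no3, fe, irr = np.broadcast_arrays(
        np.asarray(po4, float), np.asarray(no3, float),
        np.asarray(fe, float), np.asarray(irradiance, float))
    if np.any(po4 < 0) or np.any(no3 < 0) or np.any(fe < 0) or np.any(irr < 0):
        raise ValueError("negative resource concentration")
    return np.stack([
        po4 / (po4 + params.k_p),
        no3 / (no3 + params.k_n),
        fe / (fe + params.k_fe),
        irr / (irr + params.k_i),
    ])


def production_rate(factors: np.ndarray, alpha_bio: float,
                    light_in_minimum: bool = True):
    """Liebig production rate J (umol P m-3 day-1) and the limiting resource.

    ``factors`` stacks (P, N, Fe, light) on the first axis.  With
    ``light_in_minimum=False`` the light factor multiplies the nutrient
    minimum instead of competing in it.
    """
    factors = np.asarray(factors, dtype=float)
    if factors.shape[0] != 4:
        raise ValueError("expected 4 limitation factors on the first axis")
    if light_in_minimum:
        j = alpha_bio * factors.min(axis=0)
        limiter = factors.argmin(axis=0)
    else:
        nutrients = factors[:3]
        j = alpha_bio * nutrients.min(axis=0) * factors[3]
        limiter = nutrients.argmin(axis=0)
    return j, limiter


@dataclasses.dataclass
class ProductionDiagnostics:
    """Per-surface-box production and the per-box biological tendencies."""

    production: np.ndarray          # (3,) umol P m-3 day-1, order SA, SS, SP
    limiting_resource: tuple[str, ...]
    tendencies: dict[str, np.ndarray]  # per-kg unit of each tracer, per s


def bio_tendencies(state: OceanState, j: np.ndarray,
                   geom: list[BoxGeometry], params: ModelParams,
                   limiter: np.ndarray | None = None) -> ProductionDiagnostics:
    """Uptake, export and remineralization tendencies for production ``j``.

    ``j`` is the volumetric production in each surface box (SA, SS, SP;
    umol P m-3 day-1, as returned by :func:`production_rate`); tendencies
    come back in the tracer's per-kg unit per second.  Surface boxes lose
    nutrients and DIC; each deep box gains the same extensive amounts
    scaled by the volume ratio, so the global budget of every biologically
    cycled tracer closes exactly.
    """
    from .boxes import SECONDS_PER_DAY

    j = np.asarray(j, dtype=float)
    if j.shape != (3,):
        raise ValueError("j must give one production rate per surface box")
    if np.any(j < 0):
        raise ValueError("negative production")

    vol = np.array([g.volume for g in geom])
    rho = params.rho_sw
    # per-kg P rate in each box: negative = uptake, positive = remineralization
    p_rate = np.zeros(6)
    for n, s in enumerate(SURFACE):
        d = DEEP_UNDER[s]
        p_rate[s] = -j[n] / rho / SECONDS_PER_DAY
        p_rate[d] = j[n] * vol[s] / vol[d] / rho / SECONDS_PER_DAY

    # closure audit on the extensive source/sink balance
    extensive = p_rate * vol  # rho cancels
    if abs(extensive.sum()) > _CLOSURE_RTOL * max(np.abs(extensive).max(), 1e-300):
        raise AssertionError("biological export does not close")

    tend = {
        "po4": p_rate,
        "no3": params.r_n * p_rate,
        "dic": params.r_c * p_rate,
        "alk": -params.r_n * p_rate,          # uptake of NO3 raises ALK
        "fe": params.r_fe * p_rate * 1e3,     # umol P -> nmol Fe
    }
    if limiter is None:
        names = tuple("none" for _ in SURFACE)
    else:
        names = tuple(LIMITERS[i] for i in np.asarray(limiter, int))
    return ProductionDiagnostics(production=j, limiting_resource=names,
                                 tendencies=tend)


def surface_production(state: OceanState, params: ModelParams):
    """Evaluate factors, J and limiter for the three surface boxes."""
    s = list(SURFACE)
    factors = limitation_terms(state.po4[s], state.no3[s], state.fe[s],
                               np.asarray(params.irradiance)[s], params)
    j, limiter = production_rate(factors, params.alpha_bio,
                                 params.light_in_minimum)
    return factors, j, limiter
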