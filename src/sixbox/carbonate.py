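"""Seawater CO2 system, air-sea gas exchange and the atmospheric box.

Surface-ocean pCO2 is solved from DIC and total alkalinity at the
prescribed box temperature and salinity by root-finding the total-scale
hydrogen ion concentration in the alkalinity balance

    ALK = [HCO3] + 2[CO3] + [B(OH)4] + [OH] - [H]

using Weiss (1974) CO2 solubility, the Mehrbach carbonic-acid constants as
refit by Lueker et al. (2000), Dickson (1990) borate, Millero (1995) water
self-ionization, and total boron proportional to salinity (Uppstrom 1974).
Phosphate and silicate alkalinity are neglected.  The air-sea flux uses a
quadratic wind-speed piston velocity with a Schmidt-number correction.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .boxes import RHO_SW, ModelParams

#: total boron to salinity ratio, mol kg-1 per unit salinity (Uppstrom 1974)
BORON_PER_SALINITY = 0.0004157 / 35.0

#: cm hr-1 -> m s-1
_CMHR_TO_MS = 0.01 / 3600.0


def equilibrium_constants(theta, salinity) -> dict[str, np.ndarray]:
    """K0, K1, K2, KB, KW (total pH scale, mol kg-1) and total boron BT.

    ``theta`` in deg C, ``salinity`` in g kg-1; inputs broadcast.
    """
    t = np.asarray(theta, dtype=float)
    s = np.asarray(salinity, dtype=float)
    tk = t + 273.15
    tk100 = tk / 100.0
    sqs = np.sqrt(s)

    ln_k0 = (-60.2409 + 93.4517 / tk100 + 23.3585 * np.log(tk100)
             + s * (0.023517 - 0.023656 * tk100 + 0.0047036 * tk100 ** 2))
    # Lueker et al. (2000) refit of Mehrbach, total scale
    pk1 = (3633.86 / tk - 61.2172 + 9.67770 * np.log(tk)
           - 0.011555 * s + 0.0001152 * s ** 2)
    pk2 = (471.78 / tk + 25.9290 - 3.16967 * np.log(tk)
           - 0.01781 * s + 0.0001122 * s ** 2)
    ln_kb = ((-8966.90 - 2890.53 * sqs - 77.942 * s
              + 1.728 * s * sqs - 0.0996 * s ** 2) / tk
             + 148.0248 + 137.1942 * sqs + 1.62142 * s
             - (24.4344 + 25.085 * sqs + 0.2474 * s) * np.log(tk)
             + 0.053105 * sqs * tk)
    ln_kw = (148.9652 - 13847.26 / tk - 23.6521 * np.log(tk)
             + (118.67 / tk - 5.977 + 1.0495 * np.log(tk)) * sqs
             - 0.01615 * s)
    return {
        "K0": np.exp(ln_k0),
        "K1": 10.0 ** -pk1,
        "K2": 10.0 ** -pk2,
        "KB": np.exp(ln_kb),
        "KW": np.exp(ln_kw),
        "BT": BORON_PER_SALINITY * s,
    }


def alkalinity_residual(h, dic, alk, ks):
    """Residual and d(residual)/dh of the alkalinity balance (mol kg-1).

    ``h`` is total-scale [H+]; ``dic``/``alk`` in mol kg-1.
    """
    k1, k2, kb, kw, bt = ks["K1"], ks["K2"], ks["KB"], ks["KW"], ks["BT"]
    denom = h * h + k1 * h + k1 * k2
    hco3 = dic * k1 * h / denom
    co3 = dic * k1 * k2 / denom
    borate = bt * kb / (kb + h)
    res = hco3 + 2.0 * co3 + borate + kw / h - h - alk
    ddenom = 2.0 * h + k1
    dhco3 = dic * k1 * (denom - h * ddenom) / denom ** 2
    dco3 = -dic * k1 * k2 * ddenom / denom ** 2
    dres = dhco3 + 2.0 * dco3 - bt * kb / (kb + h) ** 2 - kw / h ** 2 - 1.0
    return res, dres


@dataclasses.dataclass
class CarbonateSolution:
    """Full surface carbonate speciation for one or more boxes."""

    pco2_ocean: np.ndarray   # uatm
    ph: np.ndarray           # total scale
    h_conc: np.ndarray       # mol kg-1
    co2_aq: np.ndarray       # umol kg-1
    hco3: np.ndarray         # umol kg-1
    co3: np.ndarray          # umol kg-1
    k0: np.ndarray           # mol kg-1 atm-1


def solve_carbonate(dic, alk, theta, salinity, h_init=None,
                    tol: float = 1e-12, max_iter: int = 100) -> CarbonateSolution:
    """Solve ocean pCO2 from DIC and ALK (umol kg-1) at theta (degC), S.

    Safeguarded Newton iteration on total-scale [H+]; converges to an
    alkalinity residual below ``tol`` (eq kg-1).  Raises on non-convergence
    or clearly unphysical inputs.
    """
    dic = np.asarray(dic, dtype=float) * 1e-6
    alk = np.asarray(alk, dtype=float) * 1e-6
    dic, alk, theta, salinity = np.broadcast_arrays(
        dic, alk, np.asarray(theta, float), np.asarray(salinity, float))
    if np.any((dic < 100e-6) | (dic > 8000e-6)) or np.any(np.abs(alk) > 8000e-6):
        raise ValueError("DIC/ALK outside plausible seawater range")
    if np.any((theta < -2.0) | (theta > 40.0)):
        raise ValueError("temperature outside [-2, 40] degC")
    ks = {k: np.broadcast_to(v, dic.shape).astype(float)
          for k, v in equilibrium_constants(theta, salinity).items()}

    h = np.full(dic.shape, 10.0 ** -8.0) if h_init is None \
        else np.array(h_init, dtype=float, copy=True)
    lo = np.full(dic.shape, 1e-12)
    hi = np.full(dic.shape, 1e-2)
    converged = np.zeros(dic.shape, dtype=bool)
    for _ in range(max_iter):
        res, dres = alkalinity_residual(h, dic, alk, ks)
        converged = np.abs(res) < tol
        if converged.all():
            break
        # maintain the bracket: residual decreases with h
        lo = np.where(res > 0, np.maximum(lo, h), lo)
        hi = np.where(res < 0, np.minimum(hi, h), hi)
        step = res / dres
        h_new = h - step
        bad = (h_new <= lo) | (h_new >= hi) | ~np.isfinite(h_new)
        h = np.where(bad, 0.5 * (lo + hi), h_new)
    else:
        if not converged.all():
            raise RuntimeError("carbonate solver did not converge")

    denom = h * h + ks["K1"] * h + ks["K1"] * ks["K2"]
    co2_aq = dic * h * h / denom
    hco3 = dic * ks["K1"] * h / denom
    co3 = dic * ks["K1"] * ks["K2"] / denom
    return CarbonateSolution(
        pco2_ocean=co2_aq / ks["K0"] * 1e6,
        ph=-np.log10(h),
        h_conc=h,
        co2_aq=co2_aq * 1e6,
        hco3=hco3 * 1e6,
        co3=co3 * 1e6,
        k0=ks["K0"],
    )


def schmidt_number(theta) -> np.ndarray:
    """Schmidt number of CO2 in seawater (Wanninkhof 1992 polynomial)."""
    t = np.asarray(theta, dtype=float)
    return 2073.1 - 125.62 * t + 3.6276 * t ** 2 - 0.043219 * t ** 3


def piston_velocity(wind, theta, k_pis: float, sc_correction: bool = True):
    """Gas transfer velocity, m s-1: k_pis * U^2 * (Sc/660)^-1/2."""
    k = k_pis * _CMHR_TO_MS * np.asarray(wind, float) ** 2
    if sc_correction:
        k = k * (schmidt_number(theta) / 660.0) ** -0.5
    return k


def gas_exchange_flux(pco2_ocean, pco2_atm, wind, f_open, area,
                      k_pis: float, theta, k0, rho_sw: float = RHO_SW):
    """Air-sea CO2 flux, mol C s-1 per box, positive into the ocean.

    ``pco2`` in uatm, ``k0`` in mol kg-1 atm-1, ``area`` in m2.
    """
    kw = piston_velocity(wind, theta, k_pis)
    dp = (np.asarray(pco2_atm, float) - np.asarray(pco2_ocean, float)) * 1e-6
    return kw * np.asarray(k0, float) * rho_sw * dp * np.asarray(f_open, float) \
        * np.asarray(area, float)


@dataclasses.dataclass
class AtmosphereBox:
    """Well-mixed atmospheric CO2 reservoir."""

    pco2_atm: float                  # uatm
    mode: str = "clamped"            # "clamped" | "prognostic"
    moles_per_atm: float = 1.773e20  # mol per atm of pCO2

    @property
    def carbon_inventory(self) -> float:
        """mol C."""
        return self.pco2_atm * 1e-6 * self.moles_per_atm


def atmosphere_step(atm: AtmosphereBox, total_flux_into_ocean: float,
                    dt: float) -> AtmosphereBox:
    """Advance the atmosphere one step given the net uptake (mol C s-1)."""
    if atm.mode == "clamped":
        return atm
    inventory = atm.carbon_inventory - total_flux_into_ocean * dt
    if inventory < 0:
        raise ValueError("atmospheric carbon inventory went negative")
    return AtmosphereBox(pco2_atm=inventory / atm.moles_per_atm * 1e6,
                         mode=atm.mode, moles_per_atm=atm.moles_per_atm)


def surface_constants(params: ModelParams, boxes) -> dict[str, np.ndarray]:
    """Equilibrium constants evaluated at the given boxes' theta and S."""
    idx = list(boxes)
    theta = np.asarray(params.theta)[idx]
    sal = np.asarray(params.salinity)[idx]
    return equilibrium_constants(theta, sal)
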