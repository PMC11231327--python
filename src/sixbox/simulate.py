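"""Time integration of the coupled six-box system.

All tendencies (advection/mixing, biology, iron sources and scavenging,
ligand cycling, air-sea exchange) are assembled per step and advanced with
forward Euler.  Because the prescribed circulation, biology and gas
exchange are autonomous, the fixed points of the scheme coincide with the
continuous-time equilibria, so steady states are insensitive to the step
size; this is verified by a dt-refinement test.

Biological uptake is the fastest process (uptake e-folds the limiting
nutrient in days to weeks), so production is additionally capped so that
no more than a fixed fraction of a tracer's post-transport availability
can be consumed in one step.  The cap makes the scheme unconditionally
non-negative for the biologically cycled tracers at any step size; in a
strongly limited box it reduces to supply-limited production.

Ensembles integrate many runs side by side as one batched, compiled loop
(:mod:`sixbox._kernel`), which keeps multi-hundred-kiloyear experiment
matrices at desk scale on a single core.
"""

from __future__ import annotations

import dataclasses
from typing import Any, Sequence

import numpy as np

from ._kernel import advance
from .biology import LIMITERS
from .boxes import (SECONDS_PER_DAY, SECONDS_PER_YEAR, TRACERS, BoxGeometry,
                    ModelParams, OceanState, default_geometry)
from .carbonate import equilibrium_constants, piston_velocity, solve_carbonate
from .iron import free_iron_molkg
from .transport import TransportNetwork, build_transport

#: maximum fraction of a tracer's per-step availability that biology may consume
UPTAKE_LIMIT_FRACTION = 0.9

_SURF = np.array([0, 2, 4])
_DEEP = np.array([1, 3, 5])
_IDX = {t: i for i, t in enumerate(TRACERS)}


@dataclasses.dataclass
class SteadyStateRecord:
    """Converged state plus diagnostics for one run."""

    state: OceanState
    converged: bool
    max_tendency: dict[str, float]      # normalized |dC/dt|, s-1, per tracer
    production: np.ndarray              # (3,) umol P m-3 day-1 (SA, SS, SP)
    limiting_resource: tuple[str, ...]  # per surface box
    airsea_flux: np.ndarray             # (3,) mol C s-1, positive into ocean
    pco2_ocean: np.ndarray              # (3,) uatm
    fe_free: np.ndarray                 # (6,) nmol kg-1
    years: float
    dt_days: float
    steps: int
    clamped_mass: dict[str, float]      # positivity clamping, mol per tracer
    inventory_start: dict[str, float]
    inventory_end: dict[str, float]
    history: list[dict[str, float]] = dataclasses.field(default_factory=list)

    def inventory_drift(self, key: str) -> float:
        start = self.inventory_start.get(key, 0.0)
        if start == 0.0:
            return 0.0
        return (self.inventory_end[key] - start) / start


def _resolve(params: ModelParams, net: TransportNetwork | None,
             geom: list[BoxGeometry] | None):
    if geom is None:
        geom = default_geometry()
    if net is None:
        net = build_transport(params.psi, params.f_amoc, params.f_smoc,
                              params.kappa, f_return=params.f_return)
    return net, geom


class _Batch:
    """Array-of-runs integrator state feeding the compiled kernel."""

    def __init__(self, runs: Sequence[tuple[OceanState, ModelParams,
                                            TransportNetwork | None,
                                            list[BoxGeometry] | None]]):
        from .iron import iron_sources  # local import avoids an import cycle

        b = len(runs)
        self.n = b
        self.C = np.empty((b, 6, 6))
        self.M = np.empty((b, 6, 6))
        self.mass = np.empty((b, 6))
        self.vol = np.empty((b, 6))
        self.vratio = np.empty((b, 3))
        self.alpha = np.empty(b)
        self.fI = np.empty((b, 3))
        self.srcfe = np.empty((b, 6))
        self.beta_kg = np.empty(b)
        self.kscav = np.empty(b)
        self.fecap = np.empty(b)
        self.gamma = np.empty(b)
        self.lam_dlam = np.empty((b, 6))
        self.fixed = np.empty(b, dtype=bool)
        self.lfix = np.empty(b)
        self.clamped = np.empty(b, dtype=bool)
        self.pa = np.empty(b)
        self.matm = np.empty(b)
        self.rc = np.empty(b)
        self.rn = np.empty(b)
        self.rfe = np.empty(b)
        self.kp = np.empty(b)
        self.kn = np.empty(b)
        self.kfe = np.empty(b)
        ksurf = {k: np.empty((b, 3)) for k in ("K0", "K1", "K2", "KB", "KW", "BT")}
        self.gasc = np.empty((b, 3))
        self.light_in_min = runs[0][1].light_in_minimum
        self.params = []
        self.geoms = []

        for i, (state, params, net, geom) in enumerate(runs):
            if params.light_in_minimum != self.light_in_min:
                raise ValueError("mixed light-limitation forms in one batch")
            net, geom = _resolve(params, net, geom)
            self.params.append(params)
            self.geoms.append(geom)
            self.C[i] = state.tracer_matrix()
            self.M[i] = net.matrix(geom)
            vol = np.array([g.volume for g in geom])
            area = np.array([g.area for g in geom])
            self.vol[i] = vol
            self.mass[i] = vol * params.rho_sw
            self.vratio[i] = vol[_SURF] / vol[_DEEP]
            # alpha_bio is volumetric and per model day -> mol P kg-1 s-1
            self.alpha[i] = (params.alpha_bio * 1e-6 / params.rho_sw
                             / SECONDS_PER_DAY)
            irr = np.asarray(params.irradiance)[_SURF]
            self.fI[i] = irr / (irr + params.k_i)
            self.srcfe[i] = iron_sources(geom, params) * 1e-9
            self.beta_kg[i] = params.beta * params.rho_sw
            self.kscav[i] = params.k_scav
            self.fecap[i] = (params.fe_free_cap or 0.0) * 1e-9
            self.gamma[i] = params.gamma_per_p
            self.lam_dlam[i] = params.lambda_surf * np.asarray(params.delta_lambda)
            self.fixed[i] = params.ligand_mode == "fixed"
            self.lfix[i] = params.l_fixed * 1e-9
            self.clamped[i] = state.atm_mode == "clamped"
            self.pa[i] = state.pco2_atm * 1e-6
            self.matm[i] = params.atm_moles_per_atm
            self.rc[i], self.rn[i], self.rfe[i] = params.r_c, params.r_n, params.r_fe
            self.kp[i] = params.k_p * 1e-6
            self.kn[i] = params.k_n * 1e-6
            self.kfe[i] = params.k_fe * 1e-9
            theta_s = np.asarray(params.theta)[_SURF]
            sal_s = np.asarray(params.salinity)[_SURF]
            ks = equilibrium_constants(theta_s, sal_s)
            for k in ksurf:
                ksurf[k][i] = ks[k]
            kw = piston_velocity(np.asarray(params.wind)[_SURF], theta_s,
                                 params.k_pis)
            self.gasc[i] = (kw * ks["K0"] * params.rho_sw
                            * np.asarray(params.f_open)[_SURF] * area[_SURF])
        self.ks = ksurf
        if self.fixed.any():
            self.C[self.fixed, _IDX["lig"], :] = self.lfix[self.fixed, None]
        # fully converged [H+] before stepping
        sol = solve_carbonate(self.C[:, _IDX["dic"]][:, _SURF] * 1e6,
                              self.C[:, _IDX["alk"]][:, _SURF] * 1e6,
                              np.stack([np.asarray(p.theta)[_SURF] for p in self.params]),
                              np.stack([np.asarray(p.salinity)[_SURF] for p in self.params]))
        self.H = sol.h_conc.copy()
        self.clamp_log = np.zeros((self.n, 6))  # mol clamped per tracer
        self.tend = np.zeros_like(self.C)
        self.flux = np.zeros((self.n, 3))
        self.jout = np.zeros((self.n, 3))

    # -- stepping ----------------------------------------------------------

    def advance(self, dt: float, n_steps: int, check_every: int = 2000,
                tol: float = -1.0) -> tuple[int, bool]:
        """Run the compiled kernel; returns (steps done, converged)."""
        ks = self.ks
        return advance(
            self.C, self.pa, self.H, self.M, self.mass, self.vratio,
            self.alpha, self.fI, self.srcfe, self.beta_kg, self.kscav,
            self.fecap, self.gamma, self.lam_dlam, self.fixed, self.lfix,
            self.clamped, self.matm, self.rc, self.rn, self.rfe,
            self.kp, self.kn, self.kfe,
            ks["K0"], ks["K1"], ks["K2"], ks["KB"], ks["KW"], ks["BT"],
            self.gasc, self.light_in_min, UPTAKE_LIMIT_FRACTION,
            dt, n_steps, check_every, tol,
            self.clamp_log, self.tend, self.flux, self.jout)

    # -- bookkeeping -------------------------------------------------------

    def inventories(self) -> dict[str, np.ndarray]:
        ocean = {t: (self.C[:, _IDX[t]] * self.mass).sum(axis=1) for t in TRACERS}
        return {
            "phosphorus": ocean["po4"],
            "nitrogen": ocean["no3"],
            "alkalinity": ocean["alk"],
            "carbon_ocean": ocean["dic"],
            "carbon_total": ocean["dic"] + self.pa * self.matm,
            "iron": ocean["fe"],
            "ligand": ocean["lig"],
        }

    def _pco2_ocean(self) -> np.ndarray:
        """uatm, from the current warm-started [H+]."""
        dic = self.C[:, _IDX["dic"]][:, _SURF]
        h = self.H
        k1, k2, k0 = self.ks["K1"], self.ks["K2"], self.ks["K0"]
        co2aq = dic * h * h / (h * h + k1 * h + k1 * k2)
        return co2aq / k0 * 1e6

    def normalized_tendency(self) -> np.ndarray:
        """(B, 6) max over boxes of |dC/dt| / max(C), s-1, per tracer."""
        scale = np.maximum(np.abs(self.C).max(axis=2, keepdims=True), 1e-30)
        return (np.abs(self.tend) / scale).max(axis=2)

    # -- extraction --------------------------------------------------------

    def record(self, i: int, years: float, dt_days: float, steps: int,
               converged: bool, inv0: dict[str, float],
               history: list[dict[str, float]]) -> SteadyStateRecord:
        mat = self.C[i]
        state = OceanState.from_tracer_matrix(
            mat, pco2_atm=self.pa[i] * 1e6,
            atm_mode="clamped" if self.clamped[i] else "prognostic")
        norm = self.normalized_tendency()[i]
        fefree = free_iron_molkg(mat[_IDX["fe"]], mat[_IDX["lig"]],
                                 float(self.beta_kg[i]))
        # limiting resource at the final state
        p, n, fe = (mat[_IDX[t]][_SURF] for t in ("po4", "no3", "fe"))
        factors = np.stack([p / (p + self.kp[i]),
                            n / (n + self.kn[i]),
                            fe / (fe + self.kfe[i]),
                            self.fI[i]])
        if self.light_in_min:
            limiter = factors.argmin(axis=0)
        else:
            limiter = factors[:3].argmin(axis=0)
        inv1 = {k: float(v[i]) for k, v in self.inventories().items()}
        return SteadyStateRecord(
            state=state, converged=converged,
            max_tendency={t: float(norm[_IDX[t]]) for t in TRACERS},
            production=(self.jout[i] * self.params[i].rho_sw * 1e6
                        * SECONDS_PER_DAY),
            limiting_resource=tuple(LIMITERS[k] for k in limiter),
            airsea_flux=self.flux[i].copy(),
            pco2_ocean=self._pco2_ocean()[i],
            fe_free=fefree * 1e9,
            years=years, dt_days=dt_days, steps=steps,
            clamped_mass={t: float(self.clamp_log[i, _IDX[t]]) for t in TRACERS},
            inventory_start=inv0, inventory_end=inv1, history=history)


def integrate_batch(runs, *, t_total_years: float = 100_000.0,
                    dt_days: float = 1.0, tol: float = 1e-13,
                    early_stop: bool = True, check_every: int = 2000,
                    record_every_years: float | None = None,
                    ) -> list[SteadyStateRecord]:
    """Integrate several runs side by side to ``t_total_years``.

    Each run is ``(state0, params, net, geom)`` with ``net``/``geom``
    optional (None rebuilds them from the parameters).  Integration stops
    early once every run's normalized tendency falls below ``tol``
    (disable with ``early_stop=False``); failure to reach ``tol`` within
    ``t_total_years`` is flagged on the records, not raised.  Returns one
    :class:`SteadyStateRecord` per run.
    """
    if t_total_years < 0 or dt_days <= 0:
        raise ValueError("invalid integration time or step")
    batch = _Batch(runs)
    dt = dt_days * SECONDS_PER_DAY
    n_steps = int(round(t_total_years * SECONDS_PER_YEAR / dt))
    inv0 = [{k: float(v[i]) for k, v in batch.inventories().items()}
            for i in range(batch.n)]
    histories: list[list[dict[str, float]]] = [[] for _ in range(batch.n)]
    chunk = (n_steps if record_every_years is None
             else max(1, int(record_every_years * SECONDS_PER_YEAR / dt)))
    kernel_tol = tol if early_stop else -1.0

    steps_done = 0
    converged = False
    while steps_done < n_steps:
        n = min(chunk, n_steps - steps_done)
        done, converged = batch.advance(dt, n, check_every, kernel_tol)
        steps_done += done
        if record_every_years is not None:
            inv = batch.inventories()
            for i in range(batch.n):
                histories[i].append({
                    "years": steps_done * dt / SECONDS_PER_YEAR,
                    "pco2_atm": batch.pa[i] * 1e6,
                    "carbon_total": float(inv["carbon_total"][i]),
                })
        if converged:
            break
    if steps_done and not converged:
        converged = bool(batch.normalized_tendency().max() < tol)

    years = steps_done * dt / SECONDS_PER_YEAR
    return [batch.record(i, years, dt_days, steps_done, converged, inv0[i],
                         histories[i])
            for i in range(batch.n)]


def step(state: OceanState, params: ModelParams,
         net: TransportNetwork | None = None,
         geom: list[BoxGeometry] | None = None,
         dt: float = SECONDS_PER_DAY) -> OceanState:
    """Advance one forward-Euler step of length ``dt`` seconds."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    batch = _Batch([(state, params, net, geom)])
    inv0 = {k: float(v[0]) for k, v in batch.inventories().items()}
    batch.advance(dt, 1, 2**30, -1.0)
    return batch.record(0, dt / SECONDS_PER_YEAR, dt / SECONDS_PER_DAY, 1,
                        False, inv0, []).state


def integrate_to_steady(state0: OceanState, params: ModelParams,
                        net: TransportNetwork | None = None,
                        geom: list[BoxGeometry] | None = None,
                        **kwargs: Any) -> SteadyStateRecord:
    """Integrate a single run to steady state (see :func:`integrate_batch`)."""
    return integrate_batch([(state0, params, net, geom)], **kwargs)[0]
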