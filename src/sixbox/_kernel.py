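"""Compiled inner loop of the integrator.

One jitted routine advances a whole batch of runs by many forward-Euler
steps.  The math mirrors the module-level physics operators exactly
(donor-cell transport, availability-capped Liebig production, quadratic
iron speciation, two warm-started Newton iterations of the alkalinity
balance per step, prognostic or clamped atmosphere); the surrounding
:mod:`sixbox.simulate` code owns all setup, bookkeeping and diagnostics.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# tracer indices, matching boxes.TRACERS order
DIC, ALK, PO4, NO3, FE, LIG = range(6)


@njit(cache=True)
def advance(C, pa, H, M, mass, vratio, alpha, fI, srcfe, betak, kscav, fecap,
            gamma, lamd, fixed, lfix, clamped, matm, rc, rn, rfe, kp, kn, kfe,
            k0, k1, k2, kb, kw, bt, gasc, light_in_min, cap_frac,
            dt, n_steps, check_every, tol,
            clamp_log, tend, flux, jout):  # pragma: no cover - exercised via simulate
    """Advance ``n_steps`` Euler steps; return (steps_done, converged).

    Mutates C, pa, H, clamp_log in place; ``tend``, ``flux`` and ``jout``
    hold the tendencies, air-sea fluxes and production of the last step.
    Checks the normalized-tendency convergence criterion every
    ``check_every`` steps and returns early once all runs are below
    ``tol``.
    """
    B = C.shape[0]
    scav = np.zeros((B, 6))
    converged = False
    steps = 0
    for _ in range(n_steps):
        for b in range(B):
            # transport (donor-cell fluxes + mixing, as a linear operator)
            for t in range(6):
                for i in range(6):
                    acc = 0.0
                    for j in range(6):
                        acc += M[b, i, j] * C[b, t, j]
                    tend[b, t, i] = acc

            # iron speciation and scavenging of free iron
            for i in range(6):
                ft = C[b, FE, i]
                q = betak[b] * (C[b, LIG, i] - ft) + 1.0
                fe_free = 2.0 * ft / (q + np.sqrt(q * q + 4.0 * betak[b] * ft))
                excess = fe_free - fecap[b]
                if excess < 0.0:
                    excess = 0.0
                scav[b, i] = kscav[b] * excess

            # surface carbonate system and air-sea flux
            flux_sum = 0.0
            for s in range(3):
                i = 2 * s
                dic = C[b, DIC, i]
                alk = C[b, ALK, i]
                h = H[b, s]
                for _it in range(2):
                    h2 = h * h
                    denom = h2 + k1[b, s] * h + k1[b, s] * k2[b, s]
                    hco3 = dic * k1[b, s] * h / denom
                    co3 = dic * k1[b, s] * k2[b, s] / denom
                    res = (hco3 + 2.0 * co3 + bt[b, s] * kb[b, s] / (kb[b, s] + h)
                           + kw[b, s] / h - h - alk)
                    dd = 2.0 * h + k1[b, s]
                    dres = (dic * k1[b, s] * (denom - h * dd) / (denom * denom)
                            - 2.0 * dic * k1[b, s] * k2[b, s] * dd / (denom * denom)
                            - bt[b, s] * kb[b, s] / ((kb[b, s] + h) * (kb[b, s] + h))
                            - kw[b, s] / h2 - 1.0)
                    h_new = h - res / dres
                    h = h_new if h_new > 0.0 else 0.5 * h
                H[b, s] = h
                h2 = h * h
                denom = h2 + k1[b, s] * h + k1[b, s] * k2[b, s]
                po = dic * h2 / denom / k0[b, s]
                f = gasc[b, s] * (pa[b] - po)
                flux[b, s] = f
                flux_sum += f
                tend[b, DIC, i] += f / mass[b, i]

            # biology: Liebig production with the per-step availability cap
            for s in range(3):
                i = 2 * s
                d = i + 1
                p = C[b, PO4, i]
                n = C[b, NO3, i]
                fe = C[b, FE, i]
                fp = p / (p + kp[b])
                fn = n / (n + kn[b])
                ff = fe / (fe + kfe[b])
                fmin = fp
                if fn < fmin:
                    fmin = fn
                if ff < fmin:
                    fmin = ff
                if light_in_min:
                    if fI[b, s] < fmin:
                        fmin = fI[b, s]
                    j = alpha[b] * fmin
                else:
                    j = alpha[b] * fmin * fI[b, s]
                th = cap_frac / dt
                cap = th * (p + dt * tend[b, PO4, i])
                if th * (n + dt * tend[b, NO3, i]) / rn[b] < cap:
                    cap = th * (n + dt * tend[b, NO3, i]) / rn[b]
                fe_avail = fe + dt * (tend[b, FE, i] + srcfe[b, i] - scav[b, i])
                if th * fe_avail / rfe[b] < cap:
                    cap = th * fe_avail / rfe[b]
                if cap < j:
                    j = cap
                if j < 0.0:
                    j = 0.0
                jout[b, s] = j
                jv = j * vratio[b, s]
                tend[b, DIC, i] -= rc[b] * j
                tend[b, DIC, d] += rc[b] * jv
                tend[b, ALK, i] += rn[b] * j
                tend[b, ALK, d] -= rn[b] * jv
                tend[b, PO4, i] -= j
                tend[b, PO4, d] += jv
                tend[b, NO3, i] -= rn[b] * j
                tend[b, NO3, d] += rn[b] * jv
                tend[b, FE, i] -= rfe[b] * j
                tend[b, FE, d] += rfe[b] * jv
                tend[b, LIG, i] += gamma[b] * j
                tend[b, LIG, d] += gamma[b] * jv

            # iron sources/sinks and ligand decay in every box
            for i in range(6):
                tend[b, FE, i] += srcfe[b, i] - scav[b, i]
                tend[b, LIG, i] -= lamd[b, i] * C[b, LIG, i]

            # Euler update with positivity clamping
            for t in range(6):
                deficit = 0.0
                for i in range(6):
                    cn = C[b, t, i] + dt * tend[b, t, i]
                    if cn < 0.0:
                        deficit -= cn * mass[b, i]
                        cn = 0.0
                    C[b, t, i] = cn
                if deficit > 0.0:
                    clamp_log[b, t] += deficit
                    if t <= NO3:  # conserved tracers: restore the inventory
                        pool = 0.0
                        for i in range(6):
                            pool += C[b, t, i] * mass[b, i]
                        if pool > 0.0:
                            factor = 1.0 + deficit / pool
                            for i in range(6):
                                C[b, t, i] *= factor
            if fixed[b]:
                for i in range(6):
                    C[b, LIG, i] = lfix[b]
            if not clamped[b]:
                pa[b] -= dt * flux_sum / matm[b]

        steps += 1
        if steps % check_every == 0 or steps == n_steps:
            worst = 0.0
            for b in range(B):
                for t in range(6):
                    scale = 1e-30
                    for i in range(6):
                        if C[b, t, i] > scale:
                            scale = C[b, t, i]
                    for i in range(6):
                        r = abs(tend[b, t, i]) / scale
                        if r > worst:
                            worst = r
            if not np.isfinite(worst):
                raise FloatingPointError("non-finite tendency")
            converged = worst < tol
            if converged:
                break
    return steps, converged
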