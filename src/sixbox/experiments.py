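"""Experiment matrix: overturning sweeps, perturbations and diagnostics.

The central experiment varies the Southern Ocean upwelling strength psi
between an almost-collapsed 1 Sv and a double-strength 40 Sv circulation,
once with the ligand pool fixed at 2 nmol kg-1 and once with ligands
coupled to biological activity.  Every ensemble member follows the same
protocol: equilibrate a psi = 20 Sv control for 100 kyr with the
atmosphere clamped at 280 uatm, then branch with the new psi and a
prognostic, carbon-conserving atmosphere and integrate a further 100 kyr.

Branch runs of one ensemble are integrated side by side in a single
vectorized batch, which is what makes full sweeps fast enough for
interactive use.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from typing import Any

import numpy as np
import pandas as pd

from .boxes import (BOX_NAMES, DEEP, SURFACE, BoxGeometry, ModelParams,
                    OceanState, default_geometry, default_params,
                    initial_state)
from .simulate import SteadyStateRecord, integrate_batch

#: default sweep grid (Sv); the reference control strength is 20 Sv
PSI_GRID = (1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0,
            22.0, 24.0, 25.0, 26.0, 28.0, 30.0, 32.0, 34.0, 36.0, 38.0, 40.0)

#: runs below this upwelling strength sit in the near-collapse regime and
#: are excluded from slope/anomaly statistics
PSI_REGIME_MIN = 8.0


@dataclasses.dataclass(frozen=True)
class ExperimentSpec:
    """Configuration of one ensemble sweep."""

    name: str
    ligand_mode: str = "fixed"
    psi_values: tuple[float, ...] = PSI_GRID
    reference_psi: float = 20.0
    overrides: Mapping[str, Any] = dataclasses.field(default_factory=dict)
    #: applied to branch runs only (e.g. branch-time iron-flux perturbations)
    branch_overrides: Mapping[str, Any] = dataclasses.field(default_factory=dict)
    #: box-thickness overrides, e.g. {"SA": 2000.0, "DA": 2000.0}
    geometry: Mapping[str, float] | None = None

    def control_params(self) -> ModelParams:
        ov = dict(self.overrides)
        ov["psi"] = self.reference_psi
        return default_params(self.ligand_mode, ov)

    def branch_params(self, psi: float) -> ModelParams:
        ov = dict(self.overrides)
        ov.update(self.branch_overrides)
        ov["psi"] = float(psi)
        return default_params(self.ligand_mode, ov)

    def geom(self) -> list[BoxGeometry]:
        return default_geometry(self.geometry)


@dataclasses.dataclass
class EnsembleTable:
    """One row per branch run of a sweep, plus its control."""

    spec: ExperimentSpec
    frame: pd.DataFrame
    control: SteadyStateRecord
    records: dict[float, SteadyStateRecord]

    def pco2(self, psi: float) -> float:
        return float(self.frame.set_index("psi").loc[psi, "pco2_atm"])

    def slope(self, psi_min: float = PSI_REGIME_MIN, psi_max: float = 40.0) -> float:
        """Least-squares slope of pCO2 vs psi over [psi_min, psi_max], uatm/Sv."""
        f = self.frame[(self.frame.psi >= psi_min) & (self.frame.psi <= psi_max)]
        if len(f) < 2:
            raise ValueError("need at least two runs for a slope")
        return float(np.polyfit(f.psi, f.pco2_atm, 1)[0])


def utilization_ratio(state: OceanState, geom: list[BoxGeometry],
                      tracer: str = "no3") -> float:
    """Volume-weighted mean surface / mean deep concentration ratio."""
    vol = np.array([g.volume for g in geom])
    conc = getattr(state, tracer)
    s, d = list(SURFACE), list(DEEP)
    deep = float((conc[d] * vol[d]).sum() / vol[d].sum())
    if deep == 0.0:
        raise ZeroDivisionError("deep-ocean mean concentration is zero")
    surf = float((conc[s] * vol[s]).sum() / vol[s].sum())
    return surf / deep


def nutrient_utilization(state: OceanState, geom: list[BoxGeometry],
                         tracer: str = "no3") -> float:
    """Completeness of surface nutrient consumption, 1 - surface/deep ratio.

    1 means full surface drawdown, 0 means surface concentrations as high
    as the deep ocean (no net utilization).
    """
    return 1.0 - utilization_ratio(state, geom, tracer)


def deep_mean(state: OceanState, geom: list[BoxGeometry],
              tracer: str = "fe") -> float:
    """Volume-weighted mean concentration over the three deep boxes."""
    vol = np.array([g.volume for g in geom])
    d = list(DEEP)
    return float((getattr(state, tracer)[d] * vol[d]).sum() / vol[d].sum())


def _table_row(psi: float, spec: ExperimentSpec, rec: SteadyStateRecord,
               geom: list[BoxGeometry]) -> dict[str, Any]:
    row: dict[str, Any] = {
        "psi": psi,
        "ligand_mode": spec.ligand_mode,
        "pco2_atm": rec.state.pco2_atm,
        "converged": rec.converged,
        "utilization_efficiency": nutrient_utilization(rec.state, geom),
        "utilization_ratio": utilization_ratio(rec.state, geom),
        "deep_fe_mean": deep_mean(rec.state, geom, "fe"),
    }
    for tracer in ("no3", "po4", "fe", "lig", "dic"):
        for b, name in enumerate(BOX_NAMES):
            row[f"{tracer}_{name}"] = float(getattr(rec.state, tracer)[b])
    for i, name in enumerate(("SA", "SS", "SP")):
        row[f"production_{name}"] = float(rec.production[i])
        row[f"limiter_{name}"] = rec.limiting_resource[i]
    return row


def spinup_control(spec: ExperimentSpec, *, dt_days: float = 30.0,
                   years: float = 100_000.0, tol: float = 1e-13,
                   ) -> SteadyStateRecord:
    """Equilibrate the clamped-atmosphere control state of a sweep."""
    params = spec.control_params()
    state = initial_state(params)
    return integrate_batch([(state, params, None, spec.geom())],
                           t_total_years=years, dt_days=dt_days, tol=tol,
                           early_stop=False)[0]


def run_experiments(specs: Sequence[ExperimentSpec], *, dt_days: float = 30.0,
                    years_spinup: float = 100_000.0,
                    years_branch: float = 100_000.0, tol: float = 1e-13,
                    controls: Mapping[str, SteadyStateRecord] | None = None,
                    ) -> dict[str, EnsembleTable]:
    """Run several sweeps, batching all controls and then all branches.

    ``controls`` may supply pre-computed control records keyed by spec
    name (e.g. to share one control between perturbation ensembles).
    Branch runs that fail to converge are flagged in the table, not raised.
    """
    controls = dict(controls or {})
    todo = [s for s in specs if s.name not in controls]
    if todo:
        runs = [(initial_state(s.control_params()), s.control_params(), None,
                 s.geom()) for s in todo]
        recs = integrate_batch(runs, t_total_years=years_spinup,
                               dt_days=dt_days, tol=tol, early_stop=False)
        controls.update({s.name: r for s, r in zip(todo, recs)})

    branch_runs = []
    keys = []
    for spec in specs:
        control = controls[spec.name]
        for psi in spec.psi_values:
            params = spec.branch_params(psi)
            state = control.state.copy()
            state.atm_mode = "prognostic"
            branch_runs.append((state, params, None, spec.geom()))
            keys.append((spec.name, psi))
    recs = integrate_batch(branch_runs, t_total_years=years_branch,
                           dt_days=dt_days, tol=tol, early_stop=False)

    tables: dict[str, EnsembleTable] = {}
    for spec in specs:
        geom = spec.geom()
        records = {psi: r for (name, psi), r in zip(keys, recs)
                   if name == spec.name}
        rows = [_table_row(psi, spec, r, geom) for psi, r in records.items()]
        frame = pd.DataFrame(rows).sort_values("psi").reset_index(drop=True)
        ref = (frame.set_index("psi")["pco2_atm"].get(spec.reference_psi)
               or controls[spec.name].state.pco2_atm)
        frame.insert(3, "pco2_anomaly", frame["pco2_atm"] - float(ref))
        tables[spec.name] = EnsembleTable(spec=spec, frame=frame,
                                          control=controls[spec.name],
                                          records=records)
    return tables


def run_experiment(spec: ExperimentSpec, *,
                   control: SteadyStateRecord | None = None,
                   **kwargs: Any) -> EnsembleTable:
    """Run a single sweep (see :func:`run_experiments`)."""
    controls = {spec.name: control} if control is not None else None
    return run_experiments([spec], controls=controls, **kwargs)[spec.name]


def perturbation_envelope(base_spec: ExperimentSpec, scale_up: float = 20.0,
                          scale_down: float = 1.0 / 20.0,
                          include_sp: bool = False,
                          base_table: EnsembleTable | None = None,
                          **kwargs: Any) -> dict[str, Any]:
    """Southern-Hemisphere iron-flux perturbation envelope of a sweep.

    Re-runs the sweep with the Surface Southern (optionally also Surface
    Pacific) external iron input scaled by ``scale_up`` and ``scale_down``
    at branch time, sharing the unperturbed control.  Returns the two
    tables plus a per-psi min/max pCO2 envelope (including the base sweep
    if supplied).
    """
    boxes = ("SS", "SP") if include_sp else ("SS",)

    def _spec(tag: str, scale: float) -> ExperimentSpec:
        bo = dict(base_spec.branch_overrides)
        bo["fe_input_scale"] = {b: scale for b in boxes}
        return dataclasses.replace(base_spec, name=f"{base_spec.name}_{tag}",
                                   branch_overrides=bo)

    specs = [_spec("fe_up", scale_up), _spec("fe_down", scale_down)]
    controls = None
    if base_table is not None:
        controls = {s.name: base_table.control for s in specs}
    tables = run_experiments(specs, controls=controls, **kwargs)
    up = tables[f"{base_spec.name}_fe_up"]
    down = tables[f"{base_spec.name}_fe_down"]
    frames = [up.frame, down.frame]
    if base_table is not None:
        frames.append(base_table.frame)
    stacked = pd.concat(f[["psi", "pco2_atm"]] for f in frames)
    envelope = stacked.groupby("psi")["pco2_atm"].agg(["min", "max"])
    envelope = envelope.rename(columns={"min": "pco2_min", "max": "pco2_max"})
    return {"up": up, "down": down, "envelope": envelope.reset_index()}


#: supplementary sensitivity variants (name -> control+branch overrides)
SENSITIVITY_VARIANTS: dict[str, dict[str, Any]] = {
    "atlantic_2000": {"geometry": {"SA": 2000.0, "DA": 2000.0}},
    "mixing_3sv": {"overrides": {"kappa": 3.0}},
    "alpha_low": {"overrides": {"alpha_bio": 3.0}},
    "alpha_high": {"overrides": {"alpha_bio": 9.0}},
    # lifetime perturbations are applied at branch time so that every member
    # shares the unperturbed control, mirroring the iron-flux envelope
    "ligand_slow": {"branch_overrides": {"ligand_lifetime_scale": 1.25},
                    "dynamic_only": True},
    "ligand_fast": {"branch_overrides": {"ligand_lifetime_scale": 0.75},
                    "dynamic_only": True},
}


def sensitivity_suite(variants: Sequence[str] | None = None,
                      modes: Sequence[str] = ("fixed", "dynamic"),
                      psi_values: Sequence[float] = PSI_GRID,
                      **kwargs: Any) -> dict[str, dict[str, EnsembleTable]]:
    """Run the supplementary robustness ensembles.

    Each variant (deepened Atlantic interface, 3 Sv mixing, +/-50% maximum
    production, +/-25% ligand lifetime) gets its own control spin-up; all
    sweeps run for the requested ligand modes.
    """
    variants = list(variants or SENSITIVITY_VARIANTS)
    specs = []
    for name in variants:
        cfg = SENSITIVITY_VARIANTS[name]
        for mode in modes:
            if cfg.get("dynamic_only") and mode != "dynamic":
                continue
            specs.append(ExperimentSpec(
                name=f"{name}_{mode}", ligand_mode=mode,
                psi_values=tuple(psi_values),
                overrides=cfg.get("overrides", {}),
                branch_overrides=cfg.get("branch_overrides", {}),
                geometry=cfg.get("geometry")))
    tables = run_experiments(specs, **kwargs)
    out: dict[str, dict[str, EnsembleTable]] = {}
    for name in variants:
        out[name] = {mode: tables[f"{name}_{mode}"] for mode in modes
                     if f"{name}_{mode}" in tables}
    return out
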