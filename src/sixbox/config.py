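"""Configuration files, result serialization and test fixtures.

Run configuration is a flat YAML mapping validated against
:class:`RunConfig`; unknown keys are rejected with the offending names.
Results are written as CSV tables plus a JSON manifest carrying the config
hash and a conservation audit, so a run directory is self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from collections.abc import Mapping
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .boxes import (BOX_NAMES, TRACERS, ModelParams, OceanState,
                    default_geometry, default_params, initial_state)
from .simulate import SteadyStateRecord
from .transport import build_transport


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration with defaults filled in."""

    ligand_mode: str = "fixed"
    psi: float = 20.0
    overrides: dict[str, Any] = dataclasses.field(default_factory=dict)
    experiment: str | None = None     # named sweep instead of a single run
    dt_days: float = 30.0
    years: float = 100_000.0
    tol: float = 1e-13
    out_dir: str = "results"
    seed: int = 0                     # used only by randomized fixtures

    def params(self) -> ModelParams:
        ov = dict(self.overrides)
        ov["psi"] = self.psi
        return default_params(self.ligand_mode, ov)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def load_config(path: str | pathlib.Path) -> RunConfig:
    """Read and validate a YAML run configuration.

    An empty file yields all defaults (fixed ligands, psi = 20 Sv control).
    """
    text = pathlib.Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, Mapping):
        raise ValueError(f"config {path} must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}; "
                         f"expected a subset of {sorted(known)}")
    cfg = RunConfig(**data)
    cfg.params()  # validates ligand mode and overrides
    return cfg


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def state_frame(state: OceanState) -> pd.DataFrame:
    """Final per-box concentrations as a tidy table."""
    data = {"box": BOX_NAMES}
    for t in TRACERS:
        data[t] = getattr(state, t)
    frame = pd.DataFrame(data)
    frame.attrs["pco2_atm"] = state.pco2_atm
    return frame


def write_results(tables: Mapping[str, pd.DataFrame],
                  records: Mapping[str, SteadyStateRecord],
                  out_dir: str | pathlib.Path,
                  cfg: RunConfig | None = None) -> dict[str, Any]:
    """Write CSV tables, final states and a JSON manifest; return the manifest."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for name, frame in tables.items():
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False, float_format="%.17g")
        files.append(path.name)
    audits = {}
    for name, rec in records.items():
        path = out / f"state_{name}.csv"
        state_frame(rec.state).to_csv(path, index=False, float_format="%.17g")
        files.append(path.name)
        audits[name] = {
            "converged": rec.converged,
            "pco2_atm": rec.state.pco2_atm,
            "phosphorus_drift": rec.inventory_drift("phosphorus"),
            "nitrogen_drift": rec.inventory_drift("nitrogen"),
            "carbon_drift": rec.inventory_drift("carbon_total"),
        }
    manifest = {
        "files": sorted(files),
        "config": cfg.to_dict() if cfg else None,
        "config_hash": config_hash(cfg) if cfg else None,
        "conservation_audit": audits,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def make_fixture(kind: str, seed: int = 0):
    """Deterministic synthetic inputs for tests.

    ``toy_two_box``: a mass-balanced 1 Sv two-box loop (returns volumes and
    the flux, for transport arithmetic).  ``control_like``: the tabulated
    initial six-box state with default parameters and transports.
    ``random_state``: an admissible random state for property tests.
    """
    if kind == "toy_two_box":
        return {"volumes": np.array([1.0e15, 1.0e15]), "flux_sv": 1.0}
    params = default_params("fixed")
    geom = default_geometry()
    net = build_transport(params.psi, params.f_amoc, params.f_smoc)
    if kind == "control_like":
        return initial_state(params), params, net, geom
    if kind == "random_state":
        rng = np.random.default_rng(seed)
        state = OceanState(
            dic=rng.uniform(1800, 2500, 6), alk=rng.uniform(2200, 2500, 6),
            po4=rng.uniform(0, 3, 6), no3=rng.uniform(0, 40, 6),
            fe=rng.uniform(0, 2, 6), lig=rng.uniform(0, 4, 6),
            pco2_atm=rng.uniform(180, 400), atm_mode="prognostic")
        return state, params, net, geom
    raise ValueError(f"unknown fixture kind {kind!r}")
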