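"""Shared fixtures.

The expensive pieces — full 100-kyr control spin-ups plus branch ensembles
— are computed once per session in two batched calls and reused by the
experiment, conservation and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import sixbox as sb
from sixbox.experiments import ExperimentSpec, run_experiments

#: sweep grid shared by the ensemble-level tests (Sv)
SWEEP_GRID = (8.0, 14.0, 20.0, 25.0, 32.0, 40.0)


@pytest.fixture(scope="session")
def geom():
    return sb.default_geometry()


@pytest.fixture(scope="session")
def params_fixed():
    return sb.default_params("fixed")


@pytest.fixture(scope="session")
def params_dynamic():
    return sb.default_params("dynamic")


@pytest.fixture(scope="session")
def headline():
    """Fixed- and dynamic-ligand MOC sweeps, full spin-up/branch protocol."""
    specs = [ExperimentSpec(name=mode, ligand_mode=mode, psi_values=SWEEP_GRID)
             for mode in ("fixed", "dynamic")]
    return run_experiments(specs, dt_days=30.0)


@pytest.fixture(scope="session")
def perturbations(headline):
    """Branch-time perturbation ensembles sharing the dynamic control."""
    base = headline["dynamic"]
    specs = [
        ExperimentSpec(name="lig_slow", ligand_mode="dynamic",
                       psi_values=SWEEP_GRID,
                       branch_overrides={"ligand_lifetime_scale": 1.25}),
        ExperimentSpec(name="lig_fast", ligand_mode="dynamic",
                       psi_values=SWEEP_GRID,
                       branch_overrides={"ligand_lifetime_scale": 0.75}),
        ExperimentSpec(name="fe_up", ligand_mode="dynamic",
                       psi_values=SWEEP_GRID,
                       branch_overrides={"fe_input_scale": {"SS": 20.0}}),
        ExperimentSpec(name="fe_down", ligand_mode="dynamic",
                       psi_values=SWEEP_GRID,
                       branch_overrides={"fe_input_scale": {"SS": 1.0 / 20.0}}),
    ]
    controls = {s.name: base.control for s in specs}
    return run_experiments(specs, dt_days=30.0, controls=controls)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
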