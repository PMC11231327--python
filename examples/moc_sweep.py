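"""The headline experiment: atmospheric CO2 versus overturning strength.

Sweeps the Southern Ocean upwelling strength psi from 8 to 40 Sv with
fixed and with dynamic (biologically produced) ligands.  Each member
branches from the equilibrated 20 Sv control with a prognostic,
carbon-conserving atmosphere.  Full 100-kyr legs; takes a few seconds.
"""

import numpy as np

from sixbox import ExperimentSpec, run_experiments

grid = (8.0, 14.0, 20.0, 25.0, 32.0, 40.0)
specs = [ExperimentSpec(name=mode, ligand_mode=mode, psi_values=grid)
         for mode in ("fixed", "dynamic")]
tables = run_experiments(specs, dt_days=30.0)

print("psi (Sv)   pCO2 fixed   anomaly   pCO2 dynamic   anomaly")
fixed = tables["fixed"].frame.set_index("psi")
dyn = tables["dynamic"].frame.set_index("psi")
for psi in grid:
    print(f"{psi:7.0f} {fixed.loc[psi, 'pco2_atm']:12.1f}"
          f" {fixed.loc[psi, 'pco2_anomaly']:+9.1f}"
          f" {dyn.loc[psi, 'pco2_atm']:13.1f}"
          f" {dyn.loc[psi, 'pco2_anomaly']:+9.1f}")

print()
print(f"slope over 8-40 Sv: fixed {tables['fixed'].slope():+.2f} uatm/Sv, "
      f"dynamic {tables['dynamic'].slope():+.2f} uatm/Sv")
print()
print("With a fixed ligand pool, stronger upwelling vents more deep-ocean")
print("CO2 (positive slope). Letting the biology generate its own ligands")
print("inverts the relationship: strong upwelling fuels production, ligands")
print("and iron accumulate, nutrient use becomes nearly complete, and the")
print("ocean takes carbon up instead.")
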