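# Canonical control configuration: fixed uniform ligand pool (2 nmol kg-1),
# 20 Sv Southern Ocean upwelling, atmosphere clamped at 280 uatm during
# equilibration.  Any ModelParams field can be overridden under `overrides`,
# plus the convenience keys `ligand_lifetime_scale` and `fe_input_scale`.
ligand_mode: fixed
psi: 20.0
dt_days: 30.0
years: 100000.0
tol: 1.0e-13
overrides: {}
out_dir: results
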