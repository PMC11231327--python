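# Methods

## Model structure

The ocean is discretized into six boxes: three columns (Atlantic, Southern,
Pacific) of one 100 m surface box over one 3900 m deep box, with horizontal
dimensions 17,000 km × (4,000 | 2,000 | 8,000) km. Tracers are DIC and
alkalinity (μmol kg⁻¹), phosphate and nitrate (μmol kg⁻¹), total dissolved
iron and total organic ligand (nmol kg⁻¹), plus a single well-mixed
atmospheric CO₂ reservoir. Concentrations are carried per kilogram of
seawater; volumetric rates are converted with a constant reference density
ρ = 1024.5 kg m⁻³. The model year is 360 days.

### Circulation

All transports are prescribed fractions of the Southern Ocean upwelling
strength ψ: DS→SS = ψ; SS→DS = DS→DP = DP→SP = 0.55 ψ (the SMOC);
SS→SA = SP→SA = 0.5 ψ feeding an AMOC of SA→DA = DA→DS = ψ; SP→SS = 0.05 ψ;
plus a bidirectional deep Pacific–Southern exchange DS→DP = 0.90 ψ,
DP→DS = 0.35 ψ. The last pair deserves comment, because only its difference
is constrained by the headline transports. A purely unidirectional Pacific
loop (DS→DP = DP→SP = 0.55 ψ) has the structural property that at steady
state the surface Pacific nitrate equals the deep Southern nitrate exactly —
whatever the Pacific consumes comes straight back in its own upwelling — so
the deep Pacific becomes a nutrient trap and the surface Pacific can never
approach complete drawdown. The real Pacific Deep Water circulation returns
southward at depth, and including that return flow (0.35 ψ here) restores
the deep Pacific's communication with the rest of the ocean. The directed
network is data, not code: it lives in a fractions table and serializes to
CSV, so alternative readings can be swapped in. An optional exchange κ (Sv,
default 0, 3 in the mixing sensitivity case) acts bidirectionally on all
seven adjacent pairs. Tracer advection is upstream (donor-cell); the
operator is linear and exactly volume-conserving, so source-free tracers
are conserved to round-off.

### Biology

Production in surface box i is Liebig-limited Michaelis–Menten:
J_i = α_bio · min(f_P, f_N, f_Fe, f_I) with f_X = X/(X+k_X), half
saturations k_P = 0.1 μmol kg⁻¹, k_N = 1.6 μmol kg⁻¹, k_Fe = 0.1 nmol kg⁻¹,
k_I = 30 W m⁻². A configuration switch moves light out of the minimum into
a multiplicative factor; the default keeps it in the minimum, matching the
discrete limitation regimes the system exhibits. α_bio = 6.0 μmol P m⁻³ per
model day. The per-day unit matters: read per second, the implied biomass
turnover would exceed the circulation-limited nutrient supply by six orders
of magnitude, forcing every limiting nutrient to identically zero and
making it impossible for scavenging to compete with uptake for surface
iron — inconsistent with the finite surface nitrate concentrations and the
surface iron losses this configuration is meant to produce. Per day, the
maximum global production capacity is a comfortable ~40× the realized
export, and limitation factors sit at O(0.1–1).

All export remineralizes in the directly underlying deep box (no burial,
no lateral export) with fixed stoichiometry C:N:P:Fe = 106:16:1:10⁻³.
Alkalinity responds to nitrate uptake/release only (+16 J at the surface,
−16 J·V_s/V_d at depth per unit P); there is no CaCO₃ counter-pump.
Irradiance is prescribed per box: 150 W m⁻² in the Atlantic and Pacific
surface, 50 W m⁻² in the cloudier, higher-latitude Southern surface, 0 at
depth. These values are a modeling choice (only k_I is externally
constrained); the Southern value is set low enough to matter in principle
but in practice iron remains the Liebig limiter there across the explored
regimes.

### Iron and ligands

Total iron speciates instantaneously against the ligand pool:
Fe′ + FeL = FeT, L′ + FeL = Lₜ, β′ Fe′ L′ = FeL, solved in closed form as
Fe′ = 2 FeT / (q + √(q² + 4 β′ FeT)) with q = β′(Lₜ−FeT)+1, which is free
of cancellation even when β′|Lₜ−FeT| ≫ 1; the complexed fraction is taken
from its own stable quadratic root when it is the smaller species. The
stability constant is β = 10⁹ (mol m⁻³)⁻¹, i.e. β′ = β·ρ ≈ 1.02×10¹²
(mol kg⁻¹)⁻¹ on the per-kg scale. The volumetric unit is deliberate: a
global budget closes the iron cycle at mean free iron of ~5×10⁻⁴ nmol kg⁻¹
(sources ≈ 48 mol s⁻¹ against k_scav = 10⁻⁷ s⁻¹), and only a binding
strength of this magnitude lets nmol-level total iron coexist with that
free-iron level at nmol-level ligand concentrations.

Scavenging removes free iron only, at k_scav = 10⁻⁷ s⁻¹ in every box;
scavenged iron is permanently lost. An optional hard cap treats free iron
below a configurable solubility ceiling as exempt ("precipitation above
solubility"); it is disabled by default since no threshold value is
constrained. External iron enters as S_Fe (g Fe m⁻² yr⁻¹; per box
0.300, 0.027, 0.003, 0.013, 0.030, 0.054) times the dissolving fraction
s_Fe = 2.5×10⁻³, converted with M_Fe = 55.845 g mol⁻¹ and the 360-day year.
Surface entries represent dust/sediment/river supply (Atlantic-heavy,
Southern-poor); deep entries are hydrothermal, and with s_Fe applied they
total ~4×10⁸ mol yr⁻¹, matching vent-flux estimates. The Southern
Hemisphere perturbation experiments scale the SS entry ×20 or ÷20 at
branch time (optionally also SP).

Dynamic ligands: dLₜ/dt = γ·R_P − λ δλ Lₜ, where R_P is the P-uptake rate
in surface boxes and the P-remineralization rate in deep boxes (same
coefficient for the active and passive channels), γ = 0.0053 mol L (mol
P)⁻¹, 1/λ = 8.796×10⁷ s at the surface and δλ = 0.01 (hundred-fold slower
decay) at depth. Expressed per mole of carbon, γ/λ = 4398 s (perturbed to
3298.5/5497.5 s in the lifetime sensitivity cases). Fixed mode pins
Lₜ = 2.0 nmol kg⁻¹ everywhere with no sources or sinks.

### Carbonate system and atmosphere

Ocean pCO₂ is solved from DIC and ALK at each surface box's prescribed
temperature and salinity by safeguarded Newton iteration on total-scale
[H⁺] in ALK = [HCO₃] + 2[CO₃] + [B(OH)₄] + [OH] − [H], with Weiss (1974)
K₀, Lueker et al. (2000) K₁/K₂, Dickson (1990) K_B, Millero (1995) K_W and
total boron proportional to salinity; phosphate/silicate alkalinity are
neglected at box scale. Convergence is |residual| < 10⁻¹² eq kg⁻¹. Inside
the time loop the solver is warm-started (two Newton iterations per step
from the previous [H⁺]), which stays at machine-level residuals because the
state moves slowly; a full bracketed solve initializes each run.

Air–sea flux per box is k_w K₀ ρ (pCO₂ᵃᵗᵐ − pCO₂ᵒᶜ) f_open A with
k_w = 0.337 cm hr⁻¹ (m s⁻¹)⁻² · U² · (Sc/660)^(−1/2) and the Wanninkhof
Schmidt-number polynomial; winds are 5/10/5 m s⁻¹ at the surface and the
deep boxes have f_open = 0. The atmosphere holds 1.773×10²⁰ mol per atm of
pCO₂; clamped mode fixes 280 μatm during equilibration, prognostic mode
debits exactly the integrated air–sea flux, conserving ocean+atmosphere
carbon to round-off.

## Numerics

Forward Euler on all tendencies with dt = 30 days in experiments (1 day is
the conservative default for single stepping). Because circulation,
biology, gas exchange and decay are autonomous, Euler fixed points coincide
with the continuous-time equilibria, making steady states insensitive to
dt; the dt-refinement test (30 vs 15 days, full protocol) changes steady
pCO₂ by < 10⁻³ μatm. Production is additionally capped so biology can
consume at most 90% of a tracer's post-transport availability per step,
which guarantees non-negativity for the biologically cycled tracers at any
dt and reduces to supply-limited production in strongly limited boxes.
Residual negativity (never observed in production runs) is floored at
zero, logged, and for conserved tracers repaid by rescaling the global
pool. All runs of an ensemble advance together as one batched compiled
loop; 100 kyr × 30 runs costs a few seconds on one core.

The experiment protocol is: spin up each configuration's control at
ψ = 20 Sv for 100 kyr with the atmosphere clamped at 280 μatm; branch each
ensemble member with its ψ (and any branch-time perturbation) and a
prognostic atmosphere for a further 100 kyr. Runs are integrated for the
full protocol length rather than stopped on a tendency tolerance: the
slowest adjustments (deep Pacific ventilation, deep ligand decay at
~280 yr) have per-second tendencies far below any practical tolerance long
before the state is actually steady. Consistency checks: the ψ = 20 branch
returns to 280.00 μatm; spin-ups from the tabulated and from uniform
initial tracers agree to < 0.1% per box; phosphorus, nitrogen, alkalinity
and (prognostic) total carbon drift < 10⁻⁹ relative over 100 kyr. The
lifetime and iron-flux perturbation ensembles branch from the unperturbed
control (perturbation applied at branch time), so their members are
directly comparable to the base sweep at every ψ.

## What the experiments show, and their limits

The package reproduces the qualitative structure robustly: a positive
pCO₂–ψ slope with fixed ligands and a negative slope with dynamic ligands
over 8–40 Sv; iron-limited Southern/Pacific and nitrate-limited Atlantic
surface boxes in both controls; slightly elevated ligand in the Southern
upwelling box; monotone ordering of the lifetime perturbations at every ψ;
and a ×20/÷20 Southern iron-flux envelope that adds 10–20 μatm of drawdown
at weak MOC without flipping the dynamic-mode slope.

Quantitatively, fixed-mode endpoints land within ~2–11 μatm of the
reference values, but the dynamic-mode feedback amplitude is weaker than
reported: at 40 Sv this configuration reaches ~240 μatm rather than
~190 μatm, because the surface Pacific stops ~8 μmol kg⁻¹ short of full
nitrate drawdown — the deep ocean's Fe:N ratio saturates near 1.7/16 per
nmol instead of reaching the ~2/16 that would arrest iron limitation
globally. The gap traces to the under-determined parts of the
configuration (exact transport fractions, irradiance, any additional
ligand sources), not to the mechanism. Conversely the weak-MOC outgassing
(+18 vs +30 μatm) is also damped. These deviations are asserted honestly
in the acceptance tests at the stated tolerances.

## What the model is not

There is no dynamic circulation (ψ is a knob, not a solution), no seasonal
or diurnal forcing, no ecosystem structure or variable stoichiometry, no
nitrogen fixation or denitrification, no CaCO₃ cycle, no colloidal or
particulate iron phases, no separate siderophore pool, and no carbon
isotopes. Passing tests demonstrate internal consistency and reproduction
of box-scale steady states under these idealizations; they say nothing
about spatially resolved or transient real-ocean behavior.
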