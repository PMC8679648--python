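# Methods

`polca` implements a united-atom (UA), fixed-charge force field for
tetrahedrally substituted organosilicon liquids — alkylsilanes,
alkoxysilanes, silanols and siloxanes — together with the
polarization-consistent correction calculus that turns outputs of
nonpolarizable molecular-dynamics runs into phase-change and electronic
property predictions. This note records the model, its assumptions, the
numerical choices, and what the shipped synthetic tests do and do not
demonstrate.

## The interaction model

Aliphatic CH_x groups are single interaction sites (CH3, CH2, CH, C);
hydroxyl hydrogens are explicit. Oxygens are typed by environment:
silanol O_H (Si–O–H), alkoxy O_C (Si–O–C) and bridging siloxane O_B
(Si–O–Si). Silicon sites carry an annotation k, the number of
oxygen-containing substituent groups (Si^0 … Si^4).

The energy is the usual sum

- rigid bonds: every bond is a holonomic constraint at its tabulated
  length r0 (the harmonic force constant is effectively infinite); the
  evaluator treats conformations as satisfying the constraints and
  validates rather than solves them,
- harmonic angles: U = ½ k_θ (θ − θ0)²,
- Ryckaert–Bellemans torsions: U = Σ_{n=0..5} C_n cosⁿ(ψ) with
  ψ = φ − 180°, so the trans conformation has cos ψ = 1. This is the
  convention of the GROMACS export dialect, so fitted coefficients
  round-trip through exported files unchanged. The alkylsilane backbone
  class C–C–Si–C evaluates to 0.001 kJ/mol at trans, which serves as a
  convention self-check in the tests,
- 12-6 Lennard-Jones with Lorentz–Berthelot combination (arithmetic σ,
  geometric ε),
- fixed point charges with Coulomb constant 138.935458 kJ·mol⁻¹·nm·e⁻².

Pairs separated by three bonds or fewer are fully excluded; no scaled
1-4 interactions are reintroduced (exports set `nrexcl = 3` and contain
no `[ pairs ]` section). 1-5 and longer intramolecular pairs interact
fully — e.g. the two charged methoxy terminal carbons of
dimethyldimethoxysilane.

### Charges

Substituent charges are tabulated constants (in e): −0.24 for any CH_x
on Si in a pure alkylsilane; −0.32 (CH3) and −0.27 (CH2) on Si in
oxygenated molecules; +0.25 for CH_x on an alkoxy oxygen; −0.68 (O_C),
−0.88 (O_H and O_B), +0.44 (H_O); chain alkyl groups not adjacent to Si
or O_C are neutral. The silicon charge is never tabulated: each Si
receives, at full precision, the value closing the neutrality of its own
substituent set. In multi-silicon molecules every non-Si atom is
attributed to the silicon(s) it reaches without crossing another
silicon; a bridging O_B is reachable from both and its charge is split
equally, which yields q_Si = +1.40 for hexamethyldisiloxane and
generalizes locally to larger siloxanes. Net molecular charge is zero to
1e-12 by construction.

### Lennard-Jones parameters

Si ε is 0.108 kJ/mol throughout; Si σ shrinks by 5% of the base
alkylsilane value (0.580 nm) per oxygen-containing substituent:
σ(Si^k) = 0.580·(1 − 0.05k) nm, reflecting the electron-withdrawing
character of oxygen substituents. The tabulated values (0.580, 0.551,
0.522, 0.493, 0.464 nm) are stored verbatim and the rule is used only
for validation and extrapolation beyond k = 4, avoiding rounding drift.
O_C and O_B share (0.235 nm, 1.344 kJ/mol); O_H is (0.304 nm,
1.750 kJ/mol). The hydroxyl hydrogen carries charge only (σ = ε = 0),
consistent with the alcohol lineage of this force-field family; no
published value contradicts this choice but it is a choice. Alkane CH_x
constants are carried over from the UA alkane parametrization this model
family builds on; they ship as an editable block (`alkane_lj`) in the
parameter YAML defaulting to the TraPPE-UA lineage values, and users with
the exact upstream constants should substitute them before running MD.

## Torsion parametrization

Quantum torsion scans (the upstream protocol is 12 points in 30° steps)
are reduced to a fitting target by subtracting, pointwise along the
scan, (i) classical LJ + Coulomb energies of all non-excluded pairs and
(ii) contributions of dihedral classes already parametrized, then
shifting the minimum to zero (C0 absorbs the shift). Coefficients are
obtained by unweighted linear least squares in the cosine-power basis.
On the standard 30° grid the basis has seven distinct cosine values, so
the six-coefficient fit is an exact interpolation for profiles in the
model class; rank deficiency (e.g. a grid containing only 0°/180°) is
reported as a conditioning error rather than silently regularized. A
constraint mask can pin chosen coefficients to zero for reproduction
studies; default fits use all six, and rows with trailing zeros arise
numerically.

## Polarization corrections

The model's fixed charges represent a liquid-polarized molecule, so
phase-change and electronic observables need post-facto corrections.
With dipoles μ in debye, polarizability volume α in Å³ and
ε_∞ = n_D² (squared sodium-D refractive index; never an independent
input):

- liquid dipole (Onsager continuum, cavity radius eliminated
  self-consistently via the Lorentz–Lorenz relation):
  μ_liq = μ_gas (2ε + 1)(ε_∞ + 2) / [3(2ε + ε_∞)]. This equals
  μ_gas/(1 − fα) with reaction-field factor
  fα = 2(ε−1)(ε_∞−1)/[(2ε+1)(ε_∞+2)]; the algebraic identity is used as
  a dual-route test.
- polarization energy for the gas→liquid transfer:
  E_pol = (μ_liq − μ_gas)²/(2α)
  − [(ε_∞ − 1)²/((2ε_∞ + 1)(ε_∞ + 2))] μ_liq²/α.
  The first (distortion) term is the cost of polarizing the molecular
  charge distribution and is non-negative; the second (electronic) term
  is the favorable interaction with the surrounding electron clouds and
  is non-positive. Both vanish in the no-response limit
  (μ_liq = μ_gas, ε_∞ = 1). The conversion D²/Å³ → kJ/mol is
  60.2214 (exactly 1e-19 J·N_A per D²/Å³, a numerical coincidence of
  the debye definition).
- enthalpy of vaporization: ΔH_vap = ⟨U_gas⟩ − ⟨U_liq⟩ + RT + E_pol,
  with the ideal-gas RT term (2.479 kJ/mol at 298.15 K) included.
- solvation free energy: ΔG_solv = ΔG_simul + E_pol.
- dielectric constant: ε_corr = ε_∞ + (μ_liq/μ_model)² (ε_simul − 1).
  The fluctuation term computed with the model's dipole is rescaled to
  the real liquid dipole and the electronic response is added back; the
  correction is the identity when ε_∞ = 1 and μ_model = μ_liq.

MD post-processing: ε_simul = 1 + (⟨M²⟩ − ⟨M⟩²)/(3ε0 V k_B T) from
box-dipole samples with a block-averaged (5 blocks, 2×SEM) uncertainty;
D = slope/6 of the mean-square displacement over a user-chosen window
(nm²/ps → m²/s); finite-size correction by linear extrapolation of D
versus 1/L to 1/L = 0, reporting the intercept and its standard error.

## Experimental-data curation

Literature data are reduced to 298 K values: per-source linear fits of
ρ(T) (manual exclusion flags only — no automatic outlier rule; the
mean slope doubles as a correction factor for single-temperature
values); per-source vapor-pressure fits to ln p = A + B/T with p in
mmHg, each source fitted independently so the spread of derived
enthalpies estimates the experimental uncertainty; ΔH_vap = −RB at the
window's mean temperature, shifted to 298 K by a selectable strategy
(correlation derivative, heat-capacity difference, or none — the
upstream decision cascade depends on data availability, so the package
exposes strategies rather than hard-coding an order); vapor pressure
from a normal boiling point by integrating Clausius–Clapeyron at
constant ΔH_vap with p(T_b) = 1 atm; self-solvation free energy
ΔG_solv = RT ln[p M_W/(1000 ρ R T)] (equal gas/liquid concentration
reference; p in bar at the interface, 1 bar = 750.062 mmHg fixed in one
conversion table). Aggregates report mean and 2×SEM, with no
uncertainty for n = 1. R = 8.314462618 J·mol⁻¹·K⁻¹ everywhere.

## Lennard-Jones optimizer

Per-grid-point simulated properties over a full-factorial (σ, ε) design
are fitted to second-order surfaces with cross term in coded variables
(each axis's extremes mapped linearly to [−1, 1]). The objective is the
mean squared relative deviation over all (molecule, property) pairs —
relative, because densities (~10² kg/m³) and enthalpies (~10¹ kJ/mol)
share one sum. Minimization is a two-stage steepest descent: stage 1
runs up to 4000 iterations with a variable step (initial 0.1 coded
units, ×1.2 on acceptance, ×0.5 on rejection); its best-ever point
seeds stage 2, up to 100 iterations with the step reduced tenfold. The
step-adaptation rule is a package choice — the upstream description
fixes only "variable step length" and "smaller step lengths" — and the
accepted-step objective subsequence is non-increasing by construction.
Production responses come from MD summary tables; tests plug in
synthetic quadratic surfaces through the same interface.

## Geometry and export

Single-molecule conformations are built by a deterministic
natural-extension-reference-frame embedder from constraint lengths and
equilibrium angles, with staggered default dihedrals. It provides scan
and export geometry only; it is not an energy minimizer, and
four-coordinate centers satisfy only the parent-child angle terms
exactly. Torsion profiles rotate one side of the scanned bond rigidly;
a +δ rotation increases the measured dihedral by +δ. Box packing
inserts randomly rotated rigid copies with a minimum-image distance
threshold (default 0.25 nm) under a seeded generator; identical seeds
give identical coordinates. GROMACS `.itp`/`.top`/`.gro` writers are
byte-stable. A documented NpT run template (2 fs step, 1.0 nm cutoffs
with dispersion corrections, PME, v-rescale/Parrinello–Rahman, doubled
run lengths for silanols, and the free-energy λ schedules) ships as
text in `polca/data/md_run_template.mdp` and is never executed.

## Synthetic data and what the tests show

The fixture generators plant known ground truth: torsion scans from
known RB coefficients plus a smooth periodic stand-in for 1-5
interactions; quadratic property surfaces with a shared interior
minimum over the published grid geometries; density and vapor-pressure
series from linear ρ(T) and ln p = A + B/T models, optionally with
noise and a flagged outlier. Passing round-trips demonstrate that the
analysis chain is self-consistent and numerically exact on its model
class. They do not demonstrate accuracy on real liquids: real QM scans
contain coupling the isolation step only approximately removes, real
property data carry inter-source biases, and real response surfaces are
only locally quadratic.

Two quantities are deliberately not reproducible desk-side. First,
bulk-liquid validation values (densities, enthalpies, corrected
dielectric constants, diffusion) require running the exported
topologies in an external MD engine; the corresponding test consumes
user-supplied ensemble-averaged summaries and fails informatively when
they are absent. Second, the shipped silanol dielectric-correction
inputs are labelled synthetic: the per-compound liquid/model dipole
ratio is back-derived from the published corrected/uncorrected pairs
(the primary values live in supplementary tabulations not shipped
here), so that check validates the correction formula's transcription,
not an independent prediction.

## Known limitations

- Scope: tetrahedral Si with alkyl/alkoxy/silanol/siloxane substituents
  only; SiH_x, aryl and halogen substituents, anions and protonation
  inference are rejected with scope errors.
- The intramolecular evaluator has no cutoffs, periodicity or
  electrostatic screening; it is for single-molecule scans and tests.
- The embedder's default dihedrals can place bulky groups eclipsed in
  crowded molecules; scans are relative energies about the rotated bond,
  so this affects absolute values only.
- Alkane torsion classes (e.g. C–C–C–C, relevant for substituents
  longer than ethyl) are not in the shipped table and must be supplied
  with the carried-over alkane parameters.
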