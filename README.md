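# polca

A united-atom, fixed-charge force-field toolkit for organosilicon
liquids — alkylsilanes, alkoxysilanes, silanols and siloxanes — built
around the Polarization-Consistent Approach (PolCA): a nonpolarizable
interaction model paired with *post facto* polarization corrections for
phase-change and electronic properties.

It is aimed at molecular-simulation practitioners who need parametrized
topologies of organosilicate molecules (e.g. the sol–gel precursors
TMOS/TEOS, silanols, hexamethyldisiloxane) for an external MD engine,
plus the supporting machinery of such a parametrization: torsion-profile
fitting against quantum energy scans, curation of sparse experimental
property data to 298 K, a response-surface optimizer for Lennard-Jones
parameters, and the polarization-correction calculus.

## The model in brief

Sites are CH_x united atoms, Si, three oxygen types (silanol O_H, alkoxy
O_C, bridging O_B) and explicit hydroxyl H. The potential is

U = Σ_angles ½k_θ(θ−θ₀)² + Σ_dihedrals Σₙ Cₙcosⁿ(ψ) +
Σ_pairs 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶] + Σ_pairs q_i q_j/(4πε₀r),

with all bonds rigid, ψ = φ − 180°, Lorentz–Berthelot combination, and
all pairs within three bonds excluded (no 1-4 terms). Substituent
charges are fixed constants; each silicon's charge closes molecular
neutrality exactly. Silicon σ shrinks 5% per oxygen-containing
substituent: σ(Siᵏ) = 0.580(1 − 0.05k) nm. Polarization corrections use
the Onsager continuum model: the liquid dipole
μ_liq = μ_gas(2ε+1)(ε_∞+2)/[3(2ε+ε_∞)], the correction energy
E_pol = (μ_liq−μ_gas)²/2α − (ε_∞−1)²μ_liq²/[(2ε_∞+1)(ε_∞+2)α], the
assembly ΔH_vap = ⟨U_gas⟩ − ⟨U_liq⟩ + RT + E_pol, and the dielectric
correction ε = ε_∞ + (μ_liq/μ_model)²(ε_simul − 1). Details and
assumptions: [docs/methods.md](docs/methods.md).

## Worked example

Build the trimethylsilanol topology and export GROMACS files:

```sh
$ polca build --molecule trimethylsilanol --out demo
{
  "files": {
    "itp": "demo/trimethylsilanol.itp",
    "top": "demo/trimethylsilanol.top"
  },
  "net_charge": -2.220446049250313e-16,
  "neutral": true,
  "n_sites": 6,
  "n_constraints": 5,
  "n_angles": 7,
  "n_torsions": 3,
  "n_exclusions": 15,
  "complete": true
}
```

Six sites (Si, 3×CH3, O_H, H_O); the three methyls carry −0.32 e, the
silanol oxygen −0.88 e, its hydrogen +0.44 e, and the silicon closes
neutrality at +1.40 e (visible in the `[ atoms ]` block of the `.itp`).
All five bonds are exported as constraints and the 15 exclusions are
every pair within three bonds.

Polarization corrections from experimental electronic properties
(gas-phase dipole in debye, polarizability volume in Å³, static
dielectric constant, refractive index):

```sh
$ polca correct --mu-gas 1.71 --alpha 12.4 --epsilon 7.17 --n-d 1.388
{
  "mu_liq_debye": 2.1106459631007053,
  "distortion_kjmol": 0.38978108826386654,
  "electronic_kjmol": -0.9746831571657769,
  "e_pol_kjmol": -0.5849020689019104
}
```

The condensed phase enhances the dipole from 1.71 D to 2.11 D; the
positive distortion cost (0.39 kJ/mol) is outweighed by the negative
electronic interaction (−0.97 kJ/mol), so E_pol = −0.58 kJ/mol would be
added when assembling the enthalpy of vaporization or a solvation free
energy from MD averages.

Other subcommands: `pack` (seeded box packing to `.gro`),
`fit-dihedral` (RB coefficients from a scan table), `curate` (density /
vapor-pressure series to 298 K values), `optimize-lj` (response-surface
descent), `fixtures` (synthetic data with recorded truth). The same
functionality is available as a library (`import polca`).

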