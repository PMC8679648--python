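# PolCA organosilicate parameter set.
#
# Units: lengths nm, angles deg, angle force constants kJ mol^-1 rad^-2,
# torsion coefficients kJ/mol, charges e, LJ sigma nm / epsilon kJ/mol.
#
# Substituent point charges; the silicon charge is never tabulated — it is
# computed per molecule to close overall charge neutrality.
charges:
  # Alkyl CH_x bonded to Si in a molecule with no oxygen (pure alkylsilane).
  CHx_Si_alkylsilane: -0.24
  # CH3 / CH2 bonded to Si in a silanol, alkoxysilane or siloxane molecule.
  CH3_Si_oxygenated: -0.32
  CH2_Si_oxygenated: -0.27
  # Any alkyl CH_x bonded to an alkoxy oxygen.
  CHx_O_C: 0.25
  O_C: -0.68
  O_H: -0.88
  H_O: 0.44
  O_B: -0.88
  # Alkyl groups not adjacent to Si or O_C behave as neutral alkane sites.
  CHx_chain: 0.0

# Rigid bond (constraint) lengths, nm.
bonds:
  Si-C: 0.1875
  Si-O_H: 0.1653
  Si-O_C: 0.1656
  Si-O_B: 0.1640
  C-C: 0.154
  C-O_C: 0.141
  O_H-H: 0.0945

# Harmonic angles: [theta0 (deg), k (kJ/mol/rad^2)].
angles:
  C-Si-C: [112.0, 656.2]
  Si-C-C: [111.5, 726.5]
  C-Si-O_H: [107.4, 774.6]
  Si-O_H-H: [115.5, 257.8]
  O_H-Si-O_H: [104.4, 872.6]
  Si-O_B-Si: [149.5, 61.3]
  Si-O_C-C: [124.8, 298.1]
  C-Si-O_C: [111.0, 774.6]
  O_C-Si-O_C: [105.7, 795.0]
  C-C-C: [114.0, 519.7]
  O_C-C-C: [112.0, 418.2]
  # Not tabulated for organosilicates; transferred by symmetry with the
  # alkoxy/silanol analogues for completeness of mixed substitution patterns.
  O_C-Si-O_H: [105.7, 795.0]
  O_C-Si-O_B: [105.7, 795.0]
  O_H-Si-O_B: [105.7, 795.0]
  O_B-Si-O_B: [105.7, 795.0]
  C-Si-O_B: [111.0, 774.6]

# Ryckaert-Bellemans coefficients C0..C5 per dihedral class. Class labels
# follow the i-j-k-l site classes of the dihedral ("C" = any CH_x).
torsions:
  C-C-Si-C: [1.224, 3.672, 0.0, -4.895, 0.0, 0.0]
  C-Si-O_C-C: [1.364, 4.093, 0.0, -5.457, 0.0, 0.0]
  C-C-Si-O_C: [0.692, 2.456, 0.437, -3.416, 0.0, 0.0]
  C-C-O_C-Si: [7.949, 7.892, 2.723, -18.563, 0.0, 0.0]
  C-O_C-Si-O_C: [4.314, 4.803, 0.0, -0.489, 0.0, 0.0]
  C-Si-O_H-H: [0.870, 2.600, 0.0, -3.470, 0.0, 0.0]
  C-C-Si-O_H: [0.801, 2.760, 0.508, -3.615, 0.0, 0.0]
  O_C-Si-O_H-H: [10.189, 2.939, 0.0, 6.918, 0.0, 0.0]
  C-O_C-Si-O_H: [13.021, 0.350, -39.801, -25.132, 39.605, 31.769]
  O_H-Si-O_H-H: [10.071, 6.167, 2.322, 6.236, 0.0, 0.0]
  C-C-Si-O_B: [0.692, 2.456, 0.437, -3.416, 0.0, 0.0]
  C-O_C-Si-O_B: [4.314, 4.803, 0.0, -0.489, 0.0, 0.0]
  C-Si-O_B-Si: [0.0503, 0.151, 0.0, -0.201, 0.0, 0.0]
  O_C-Si-O_B-Si: [10.607, 0.420, 0.0, 10.187, 0.0, 0.0]
  O_B-Si-O_B-Si: [10.607, 0.420, 0.0, 10.187, 0.0, 0.0]
  O_H-Si-O_B-Si: [14.871, 8.170, 0.0, 6.700, 0.0, 0.0]

# Lennard-Jones parameters, stored verbatim; the per-oxygenated-substituent
# sigma scaling rule is kept separately for validation and extrapolation.
lj:
  Si^0: [0.580, 0.108]
  Si^1: [0.551, 0.108]
  Si^2: [0.522, 0.108]
  Si^3: [0.493, 0.108]
  Si^4: [0.464, 0.108]
  O_C: [0.235, 1.344]
  O_B: [0.235, 1.344]
  O_H: [0.304, 1.750]
  # Hydroxyl hydrogen carries charge only.
  H_O: [0.0, 0.0]

# Fractional sigma reduction of Si per oxygen-containing substituent group.
si_sigma_scaling_per_oxy: 0.05

# Carried-over united-atom alkane constants (editable; defaults follow the
# TraPPE-UA lineage the alkane parametrization of this force-field family is
# based on). Replace with the exact upstream values if you have them.
alkane_lj:
  CH3: [0.375, 0.8148]
  CH2: [0.395, 0.3825]
  CH: [0.468, 0.0831]
  C: [0.640, 0.0042]
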